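"""DMS-seq signal processing: reactivity normalization, unpaired-base calls,
coverage filtering, and replicate reproducibility.

DMS methylates unpaired adenosines and cytosines, so only A/C positions carry
structural information; G/U positions are retained in profiles but never
called.  Raw per-base counts are normalized per scored region: values above
the region's 95th percentile are capped at that percentile (one-sided
Winsorization), then everything is divided by the resulting maximum, giving
reactivities in [0, 1].  A/C bases whose normalized reactivity exceeds 0.2
are called unpaired.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import CountTrack, GenomeAnnotation, Orf, ReactivityProfile, orf_profile

UNPAIRED_THRESHOLD = 0.2
MIN_COVERAGE = 15.0


def normalize_reactivity(
    raw: np.ndarray, bases: str, winsor_quantile: float = 0.95
) -> ReactivityProfile:
    """Normalize raw per-base counts of one region to [0, 1].

    The quantile uses linear interpolation between order statistics (the
    numpy default), fixed here because the percentile is method-ambiguous at
    small n.  An all-zero region yields an all-zero profile.
    """
    v = np.asarray(raw, dtype=float)
    if v.size == 0:
        raise ValueError("empty region")
    if (v < 0).any():
        raise ValueError("negative raw counts")
    coverage = float(v.mean())
    if v.max() == 0:
        return ReactivityProfile(values=np.zeros_like(v), bases=bases, coverage=coverage)
    cap = np.quantile(v, winsor_quantile)
    capped = np.minimum(v, cap)
    peak = capped.max()
    if peak == 0:
        # degenerate: >95% of positions are zero; fall back to the raw max
        capped, peak = v, v.max()
    return ReactivityProfile(values=capped / peak, bases=bases, coverage=coverage)


def call_unpaired(
    profile: ReactivityProfile, threshold: float = UNPAIRED_THRESHOLD
) -> ReactivityProfile:
    """Set unpaired calls at A/C positions: call = (reactivity > threshold).

    The call array is meaningful only where ``profile.is_ac``; other entries
    are False and carry no information.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    call = (profile.values > threshold) & profile.is_ac
    profile.unpaired_call = call
    return profile


def orf_reactivity(
    track: CountTrack,
    annotation: GenomeAnnotation,
    orf: Orf | str,
    threshold: float = UNPAIRED_THRESHOLD,
) -> ReactivityProfile:
    """Normalized, called reactivity profile of one ORF."""
    if isinstance(orf, str):
        orf = annotation.orf(orf)
    raw = orf_profile(track, orf)
    profile = normalize_reactivity(raw, annotation.orf_sequence(orf))
    return call_unpaired(profile, threshold=threshold)


def mean_coverage(track: CountTrack, orf: Orf) -> float:
    """Mean raw reads per nucleotide over the ORF body."""
    return float(orf_profile(track, orf).mean())


def coverage_filter(
    track: CountTrack, annotation: GenomeAnnotation, min_mean: float = MIN_COVERAGE
) -> list[str]:
    """ORF ids whose mean raw reads/nt over the ORF is >= ``min_mean``.

    The bound is inclusive, so an ORF at exactly the cutoff is kept.
    """
    return [o.id for o in annotation.orfs if mean_coverage(track, o) >= min_mean]


def coverage_table(track: CountTrack, annotation: GenomeAnnotation,
                   min_mean: float = MIN_COVERAGE) -> pd.DataFrame:
    rows = [
        {"orf_id": o.id, "mean_coverage": mean_coverage(track, o),
         "included": mean_coverage(track, o) >= min_mean}
        for o in annotation.orfs
    ]
    return pd.DataFrame(rows)


def reproducibility_curve(
    rep1: CountTrack,
    rep2: CountTrack,
    annotation: GenomeAnnotation,
    cutoffs: list[float],
    region_len: int = 200,
) -> pd.DataFrame:
    """Replicate agreement as a function of sequencing depth.

    For each depth cutoff, Pearson's R between the two replicates' raw
    signal over the first ``region_len`` nt of each ORF passing the cutoff
    in both replicates (shorter ORFs use their full length); the median R
    across qualifying ORFs is reported.  A cutoff with no qualifying ORFs
    yields NaN rather than failing.
    """
    per_orf = []
    for orf in annotation.orfs:
        p1, p2 = orf_profile(rep1, orf), orf_profile(rep2, orf)
        cov1, cov2 = p1.mean(), p2.mean()
        L = min(region_len, orf.length)
        a, b = p1[:L], p2[:L]
        if np.std(a) == 0 or np.std(b) == 0:
            r = np.nan
        else:
            r = sps.pearsonr(a, b).statistic
        per_orf.append((min(cov1, cov2), r))
    rows = []
    for cutoff in cutoffs:
        rs = [r for cov, r in per_orf if cov >= cutoff and np.isfinite(r)]
        rows.append(
            {"cutoff": cutoff, "median_r": float(np.median(rs)) if rs else np.nan,
             "n_orfs": len(rs)}
        )
    return pd.DataFrame(rows)
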
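"""Same-message detection for adjacent ORFs from mRNA-seq coverage.

Annotated operon membership does not guarantee two adjacent ORFs actually
share a transcript (internal promoters and terminators split operons).  Two
coverage-based tests decide, each calibrated against within-ORF variability
so the cutoffs adapt to the dataset's depth and noise:

* level equivalence: |log2 ratio| of the pair's mean mRNA densities must
  fall within 2 sigma of the distribution of within-ORF first-half vs
  second-half log2 ratios;
* signal continuity: the Gini index of every 80-nt window covering the
  intergenic gap must fall within mean + 2 sigma of the distribution of
  80-nt window Ginis inside ORF bodies.  Overlapping pairs have no gap and
  skip this test.  A gap window with no signal at all is a discontinuity by
  definition and fails.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gini import gini_value, windowed_gini
from .model import CountTrack, GenomeAnnotation, Orf, orf_profile, spacing


@dataclass
class LevelCutoff:
    sigma_log2: float
    n_orfs: int

    @property
    def cutoff_log2(self) -> float:
        return 2.0 * self.sigma_log2

    @property
    def fold_cutoff(self) -> float:
        """The 2-sigma cutoff expressed as a fold change."""
        return float(2.0**self.cutoff_log2)


@dataclass
class ContinuityCutoff:
    mean: float
    sigma: float
    n_windows: int

    @property
    def cutoff(self) -> float:
        return self.mean + 2.0 * self.sigma


def calibrate_level_cutoff(
    track: CountTrack,
    annotation: GenomeAnnotation,
    min_orfs: int = 30,
    min_coverage: float = 1.0,
) -> LevelCutoff:
    """2-sigma mean-level cutoff from within-ORF half-vs-half variability."""
    ratios = []
    for orf in annotation.orfs:
        prof = orf_profile(track, orf)
        if prof.mean() < min_coverage:
            continue
        mid = prof.size // 2
        m1, m2 = prof[:mid].mean(), prof[mid:].mean()
        if m1 > 0 and m2 > 0:
            ratios.append(np.log2(m1 / m2))
    if len(ratios) < min_orfs:
        raise ValueError(
            f"need >= {min_orfs} covered ORFs to calibrate, got {len(ratios)}"
        )
    return LevelCutoff(sigma_log2=float(np.std(ratios)), n_orfs=len(ratios))


def calibrate_continuity_cutoff(
    track: CountTrack,
    annotation: GenomeAnnotation,
    window: int = 80,
    step: int = 40,
    min_orfs: int = 30,
    min_coverage: float = 1.0,
) -> ContinuityCutoff:
    """2-sigma window-Gini cutoff from windows inside ORF bodies."""
    ginis: list[float] = []
    n_used = 0
    for orf in annotation.orfs:
        prof = orf_profile(track, orf)
        if prof.size < window or prof.mean() < min_coverage:
            continue
        _, g = windowed_gini(prof, window=window, step=step)
        g = g[np.isfinite(g)]
        if g.size:
            ginis.extend(g.tolist())
            n_used += 1
    if n_used < min_orfs:
        raise ValueError(
            f"need >= {min_orfs} ORFs longer than the {window} nt window, got {n_used}"
        )
    arr = np.asarray(ginis)
    return ContinuityCutoff(
        mean=float(arr.mean()), sigma=float(arr.std()), n_windows=arr.size
    )


def _gap_window_ginis(
    track: CountTrack, up: Orf, down: Orf, window: int, step: int
) -> np.ndarray:
    """Ginis of windows whose centers tile the intergenic gap.

    Windows are full-length (they reach into the flanking ORFs); an
    all-zero window yields NaN from the Gini and is mapped to +inf here so
    it always fails the continuity cutoff.
    """
    arr = track.array(up.replicon, up.strand)
    if up.strand == "+":
        gap_lo, gap_hi = up.end, down.start
    else:
        gap_lo, gap_hi = down.end, up.start
    centers = np.arange(gap_lo, gap_hi, step)
    out = []
    half = window // 2
    for c in centers:
        lo, hi = max(0, c - half), min(arr.size, c - half + window)
        g = gini_value(arr[lo:hi])
        out.append(np.inf if not np.isfinite(g) else g)
    return np.asarray(out)


def same_message_pairs(
    track: CountTrack,
    annotation: GenomeAnnotation,
    level: LevelCutoff | None = None,
    continuity: ContinuityCutoff | None = None,
    window: int = 80,
    step: int = 40,
) -> pd.DataFrame:
    """PairTable: one row per adjacent operon pair with the same-message call.

    Cutoffs are calibrated from the track itself when not supplied.
    """
    if level is None:
        level = calibrate_level_cutoff(track, annotation)
    if continuity is None:
        continuity = calibrate_continuity_cutoff(track, annotation, window, step)
    rows = []
    for up, down in annotation.adjacent_pairs():
        sp = spacing(up, down)
        m_up = orf_profile(track, up).mean()
        m_down = orf_profile(track, down).mean()
        if m_up > 0 and m_down > 0:
            log2_ratio = float(np.log2(m_down / m_up))
        else:
            log2_ratio = np.inf
        level_ok = abs(log2_ratio) <= level.cutoff_log2
        if sp <= 0:
            max_gap_gini, continuity_ok = np.nan, True  # no gap to test
        else:
            ginis = _gap_window_ginis(track, up, down, window, step)
            max_gap_gini = float(ginis.max()) if ginis.size else np.nan
            continuity_ok = bool((ginis <= continuity.cutoff).all())
        rows.append(
            {
                "upstream_id": up.id, "downstream_id": down.id, "operon": up.operon,
                "spacing": sp,
                "overlap_class": "overlapping" if sp <= 0 else "non_overlapping",
                "log2_level_ratio": log2_ratio, "max_gap_gini": max_gap_gini,
                "level_ok": level_ok, "continuity_ok": continuity_ok,
                "same_message": bool(level_ok and continuity_ok),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "upstream_id", "downstream_id", "operon", "spacing", "overlap_class",
            "log2_level_ratio", "max_gap_gini", "level_ok", "continuity_ok",
            "same_message",
        ],
    )


def classify_overlap(pairs: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Overlap classes plus the empirical CDF of spacings."""
    df = pairs.copy()
    df["overlap_class"] = np.where(df["spacing"] <= 0, "overlapping", "non_overlapping")
    sp = np.sort(df["spacing"].to_numpy())
    cdf = pd.DataFrame(
        {"spacing": sp, "cum_fraction": np.arange(1, sp.size + 1) / max(sp.size, 1)}
    )
    return df, cdf


def flag_discontinuous_genes(
    track: CountTrack,
    annotation: GenomeAnnotation,
    min_coverage: float = 1.0,
) -> pd.DataFrame:
    """Flag genes whose whole-body mRNA-seq Gini exceeds mean + 2 sigma of
    the cohort (early terminators / internal promoters)."""
    rows = []
    for orf in annotation.orfs:
        prof = orf_profile(track, orf)
        g = gini_value(prof) if prof.mean() >= min_coverage else np.nan
        rows.append({"orf_id": orf.id, "mrna_gini": g})
    df = pd.DataFrame(rows)
    vals = df["mrna_gini"].to_numpy()
    ok = np.isfinite(vals)
    if ok.sum() >= 2:
        cutoff = float(vals[ok].mean() + 2.0 * vals[ok].std())
    else:
        cutoff = np.inf
    df["discontinuous"] = np.where(ok, vals > cutoff, False)
    df.attrs["cutoff"] = cutoff
    return df
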
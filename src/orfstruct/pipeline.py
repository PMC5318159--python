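"""Configuration-driven orchestration of the full analysis.

Stages: simulate (or load) data -> DMS signal -> Gini structure scores ->
operon same-message pairs -> expression/TE -> boundary folding statistics ->
correlation/regression reports.  Every output table is TSV with a leading
comment line carrying the config hash, so any result can be traced to the
exact configuration that produced it; a ``manifest.json`` accumulates the
stage log.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import dms, expression, fold, gini, operons, simulate, stats
from .codon import relative_adaptiveness, tai_table
from .simulate import FixtureBundle

log = logging.getLogger("orfstruct")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "n_operons": 40,
        "orfs_per_operon": [2, 4],
        "orf_len": [300, 600],
        "overlap_fraction": 0.15,
        "paired_fraction": [0.0, 0.8],
        "dms_depth": 30.0,
        "mrna_depth": 50.0,
        "ribo_depth": 50.0,
        "dispersion": 0.2,
        "te_model": [0.0, 4.0, 0.3],
        "break_fraction": 0.1,
        "n_dms_replicates": 2,
    },
    "thresholds": {
        "unpaired": 0.2,       # normalized reactivity above which A/C is unpaired
        "min_coverage": 15.0,  # DMS reads/nt required to score an ORF
        "min_reads": 128,      # footprint reads required for a TE value
    },
    "windows": {
        "directionality": 60,
        "continuity": 80,
        "rolling_gini": 100,
        "boundary_scan": 300,
        "flank": 250,
    },
    "samples": {"dms": "dms", "mrna": "mrna", "ribo": "ribo", "ksg_dms": None},
    "folding": {"beta": 2.0, "engine": "internal", "max_pairs": 12},
}


def merge_config(overrides: dict | None = None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for key, val in (overrides or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, stage: str, chash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# orfstruct stage={stage} config={chash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


class PipelineRun:
    """One configured run over one dataset."""

    def __init__(self, config: dict | None = None, outdir: str | Path = "."):
        self.config = merge_config(config)
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.chash = config_hash(self.config)
        self.stage_log: list[str] = []
        self.bundle: FixtureBundle | None = None

    # -- helpers ----------------------------------------------------------

    def _log(self, msg: str) -> None:
        log.info(msg)
        self.stage_log.append(msg)

    def _save(self, df: pd.DataFrame, name: str, stage: str) -> Path:
        path = self.outdir / name
        _write_table(df, path, stage, self.chash)
        return path

    def _track(self, role: str):
        name = self.config["samples"][role]
        if name is None:
            return None
        if self.bundle is None or name not in self.bundle.tracks:
            raise FileNotFoundError(f"sample {name!r} (role {role}) not in dataset")
        return self.bundle.tracks[name]

    # -- stages -----------------------------------------------------------

    def simulate(self) -> FixtureBundle:
        sim = self.config["simulate"]
        self.bundle = simulate.make_dataset(
            seed=self.config["seed"],
            n_operons=sim["n_operons"],
            orfs_per_operon=tuple(sim["orfs_per_operon"]),
            orf_len=tuple(sim["orf_len"]),
            overlap_fraction=sim["overlap_fraction"],
            paired_fraction=tuple(sim["paired_fraction"])
            if isinstance(sim["paired_fraction"], (list, tuple))
            else sim["paired_fraction"],
            dms_depth=sim["dms_depth"],
            mrna_depth=sim["mrna_depth"],
            ribo_depth=sim["ribo_depth"],
            dispersion=sim["dispersion"],
            te_model=tuple(sim["te_model"]),
            break_fraction=sim["break_fraction"],
            n_dms_replicates=sim["n_dms_replicates"],
        )
        data_dir = self.outdir / "data"
        simulate.write_fixture(self.bundle, data_dir)
        self._log(f"simulate: wrote fixture to {data_dir}")
        return self.bundle

    def load(self, data_dir: str | Path) -> FixtureBundle:
        self.bundle = simulate.read_fixture(data_dir)
        self._log(f"load: read fixture from {data_dir}")
        return self.bundle

    def signal(self) -> pd.DataFrame:
        ann = self.bundle.annotation
        track = self._track("dms")
        thr = self.config["thresholds"]
        cov = dms.coverage_table(track, ann, min_mean=thr["min_coverage"])
        calls = []
        for orf in ann.orfs:
            prof = dms.orf_reactivity(track, ann, orf, threshold=thr["unpaired"])
            calls.append(
                {"orf_id": orf.id, "n_ac": int(prof.is_ac.sum()),
                 "n_unpaired": int(prof.unpaired_call.sum())}
            )
        out = cov.merge(pd.DataFrame(calls), on="orf_id")
        self._save(out, "signal.tsv", "signal")
        self._log(f"signal: {int(out['included'].sum())}/{len(out)} ORFs pass coverage")
        return out

    def gini(self) -> pd.DataFrame:
        ann = self.bundle.annotation
        track = self._track("dms")
        thr = self.config["thresholds"]
        included = set(dms.coverage_filter(track, ann, thr["min_coverage"]))
        ksg = self._track("ksg_dms")
        rows = []
        for orf in ann.orfs:
            if orf.id not in included:
                continue
            prof = dms.orf_reactivity(track, ann, orf)
            g = gini.ac_gini(prof)
            g1, g2 = gini.orf_half_ginis(prof)
            row = {"orf_id": orf.id, "operon": orf.operon, "gini": g,
                   "gini_first_half": g1, "gini_second_half": g2}
            if ksg is not None:
                gk = gini.ac_gini(dms.orf_reactivity(ksg, ann, orf))
                row["gini_untranslated"] = gk
                row["delta_gini"] = gini.delta_gini(gk, g)
            rows.append(row)
        out = pd.DataFrame(rows)
        self._save(out, "gini.tsv", "gini")
        note = "with" if ksg is not None else "without"
        self._log(f"gini: scored {len(out)} ORFs ({note} untranslated sample)")
        return out

    def operons(self) -> pd.DataFrame:
        ann = self.bundle.annotation
        track = self._track("mrna")
        win = self.config["windows"]["continuity"]
        level = operons.calibrate_level_cutoff(track, ann)
        cont = operons.calibrate_continuity_cutoff(track, ann, window=win)
        pairs = operons.same_message_pairs(track, ann, level, cont, window=win)
        pairs, cdf = operons.classify_overlap(pairs)
        disc = operons.flag_discontinuous_genes(track, ann)
        self._save(pairs, "pairs.tsv", "operons")
        self._save(cdf, "spacing_cdf.tsv", "operons")
        self._save(disc, "discontinuous.tsv", "operons")
        self._log(
            f"operons: {int(pairs['same_message'].sum())}/{len(pairs)} same-message "
            f"pairs (level cutoff {level.fold_cutoff:.2f}-fold)"
        )
        return pairs

    def te(self, pairs: pd.DataFrame | None = None) -> pd.DataFrame:
        ann = self.bundle.annotation
        cfg = expression.CorrectionConfig(
            min_reads=self.config["thresholds"]["min_reads"]
        )
        table = expression.expression_table(
            self._track("ribo"), self._track("mrna"), ann, cfg
        )
        self._save(table, "expression.tsv", "te")
        if pairs is None:
            pairs = expression.te_pairs_from_annotation(ann)
        ratios, ks_stat, ks_p = expression.adjacent_te_ratios(pairs, table)
        ratios.attrs["ks"] = (ks_stat, ks_p)
        self._save(ratios, "te_ratios.tsv", "te")
        self._log(
            f"te: {int(np.isfinite(table['te']).sum())}/{len(table)} ORFs with TE; "
            f"overlap-class K-S p={ks_p:.3g}"
        )
        return table

    def boundary(self, pairs: pd.DataFrame | None = None) -> pd.DataFrame:
        ann = self.bundle.annotation
        track = self._track("dms")
        foldcfg = self.config["folding"]
        flank = self.config["windows"]["flank"]
        window = self.config["windows"]["directionality"]
        if pairs is None:
            pairs = expression.te_pairs_from_annotation(ann)
            pairs["same_message"] = True
        usable = pairs[pairs["same_message"]]
        boundaries = []
        for r in usable.itertuples():
            up, down = ann.orf(r.upstream_id), ann.orf(r.downstream_id)
            try:
                bw = fold.fold_boundary(
                    ann, up, down, dms_track=track, flank=flank,
                    beta=foldcfg["beta"], engine=foldcfg["engine"],
                )
            except ValueError as exc:
                self._log(f"boundary: skipped {up.id}-{down.id}: {exc}")
                continue
            boundaries.append(bw)
            if len(boundaries) >= foldcfg["max_pairs"]:
                break
        profile = fold.directionality_profile(boundaries, window=window)
        meta = fold.metagene_pairing(boundaries)
        self._save(profile, "directionality.tsv", "boundary")
        self._save(meta, "metagene.tsv", "boundary")
        self._log(f"boundary: folded {len(boundaries)} pair windows")
        return profile

    def stats(
        self, gini_table: pd.DataFrame, expr_table: pd.DataFrame
    ) -> dict:
        merged = gini_table.merge(expr_table, on="orf_id").dropna(
            subset=["gini", "te"]
        )
        merged = merged[merged["te"] > 0]
        report: dict = {"n_orfs": int(len(merged))}
        if len(merged) >= 5:
            boot = stats.spearman_bootstrap(
                merged["gini"].to_numpy(), np.log(merged["te"].to_numpy()),
                seed=self.config["seed"],
            )
            report["spearman_te_gini"] = boot.rho
            report["spearman_ci"] = [boot.ci_low, boot.ci_high]
            weights = relative_adaptiveness()
            tais = tai_table(self.bundle.annotation, weights).set_index("orf_id")
            feats = pd.DataFrame(
                {
                    "gini": merged["gini"].to_numpy(),
                    "tai": tais.reindex(merged["orf_id"])["tai"].to_numpy(),
                },
                index=merged.index,
            )
            complete = feats.notna().all(axis=1)
            if complete.sum() >= 20:
                steps = stats.stepwise_te_regression(
                    feats[complete], merged.loc[complete, "te"].to_numpy()
                )
                self._save(steps, "stepwise.tsv", "stats")
                report["stepwise_r2"] = steps["r_squared"].tolist()
        with open(self.outdir / "stats.json", "w") as fh:
            json.dump(report, fh, indent=1)
        self._log(f"stats: report on {report['n_orfs']} ORFs")
        return report

    # -- entry point -------------------------------------------------------

    def run_all(self, data_dir: str | Path | None = None) -> dict:
        if data_dir is not None:
            self.load(data_dir)
        else:
            self.simulate()
        self.signal()
        gini_table = self.gini()
        pairs = self.operons()
        expr = self.te(pairs)
        self.boundary(pairs)
        report = self.stats(gini_table, expr)
        manifest = {
            "config": self.config, "config_hash": self.chash,
            "stages": self.stage_log,
        }
        with open(self.outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        return report
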
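"""End-to-end orchestration: cohort -> exclusions -> deltas -> limits -> validation -> RCV.

``run_pipeline`` executes the whole flow from a serializable ``RunConfig``
and writes a report bundle to an output directory:

* ``dcls.json`` — group and combined limits per analyte and metric;
* ``validation.tsv`` — own-group, cross-group and combined applications
  with proportions outside and chi-squared / quantile-regression p-values;
* ``sex_percentiles.tsv`` — two-sided signed-delta percentiles by sex;
* ``rcv.tsv`` — asymmetric reference change values at 95% and 99%;
* ``exclusions.json`` — the exclusion log;
* ``manifest.json`` — config, seeds and package version, so a persisted
  config re-executes to identical outputs;
* optional histograms of each metric with the group and combined limits
  overlaid (``plots/``).
"""

from __future__ import annotations

import dataclasses
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .deltas import METRIC_COLUMNS, compute_deltas
from .estimation import (DclEstimate, combine_dcls, estimate_dcls,
                         sex_stratified_percentiles, split_dev_val)
from .io import apply_exclusions, read_pairs, write_pairs
from .rcv import BioVariationInput, rcv_table
from .synthetic import CohortConfig, generate_cohort
from .validation import chisq_compare, cross_validate, proportion_outside, \
    quantreg_group_test

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Serializable description of one pipeline run.

    Exactly one of ``input_csv`` / ``generator`` must be set.  ``metrics``
    selects which delta statistics are analyzed; ``validation_modes`` any of
    ``own``, ``cross``, ``combined``.
    """

    input_csv: str | None = None
    generator: CohortConfig | None = None
    min_interval_days: float = 1.0
    max_interval_days: float = 1095.0
    min_age: int = 19
    min_group_n: int = 1000
    split_ratio: float = 0.6
    split_seed: int = 42
    percentile: float = 95.0
    metrics: tuple[str, ...] = ("absDD", "absDPC")
    validation_modes: tuple[str, ...] = ("own", "cross", "combined")
    chisq_correction: bool = False
    quantreg: bool = True
    n_boot: int = 1000
    bootstrap_seed: int = 42
    bio_variation: tuple[BioVariationInput, ...] = ()
    make_plots: bool = False

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.generator is None):
            raise ValueError("set exactly one of input_csv or generator")
        unknown = set(self.metrics) - set(METRIC_COLUMNS)
        if unknown:
            raise ValueError(f"unknown metrics: {sorted(unknown)}")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        if self.generator is not None:
            d["generator"] = json.loads(self.generator.to_json())
        d["bio_variation"] = [dataclasses.asdict(b) for b in self.bio_variation]
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if d.get("generator") is not None:
            d["generator"] = CohortConfig.from_json(json.dumps(d["generator"]))
        d["bio_variation"] = tuple(
            BioVariationInput(
                **{**b, "cv_i_ci": _tup(b.get("cv_i_ci")),
                   "cv_a_ci": _tup(b.get("cv_a_ci"))}
            )
            for b in d.get("bio_variation", [])
        )
        for key in ("metrics", "validation_modes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _tup(x):
    return tuple(x) if x is not None else None


def _dcl_record(d: DclEstimate) -> dict:
    return {"analyte": d.analyte, "group": d.group, "metric": d.metric,
            "percentile": d.percentile, "limit": d.limit, "n_dev": d.n_dev}


def _plot_distributions(deltas, dcls, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir.mkdir(parents=True, exist_ok=True)
    by_key = {(d.analyte, d.metric, d.group): d.limit for d in dcls}
    for analyte, sub in deltas.groupby("analyte"):
        for metric, col in METRIC_COLUMNS.items():
            if (analyte, metric, "IE") not in by_key and \
               (analyte, metric, "O") not in by_key:
                continue
            fig, ax = plt.subplots(figsize=(6, 4))
            for group, color in (("IE", "tab:blue"), ("O", "tab:orange")):
                vals = sub.loc[sub["group"] == group, col]
                if len(vals) == 0:
                    continue
                ax.hist(vals, bins=80, alpha=0.5, label=group, color=color,
                        density=True)
                lim = by_key.get((analyte, metric, group))
                if lim is not None:
                    ax.axvline(lim, color="red", linestyle="--")
            comb = by_key.get((analyte, metric, "combined"))
            if comb is not None:
                ax.axvline(comb, color="purple", linestyle="--",
                           label="combined DCL")
            ax.set_xlabel(metric)
            ax.set_title(analyte)
            ax.legend()
            fig.tight_layout()
            fig.savefig(outdir / f"{analyte}_{metric}.png", dpi=100)
            plt.close(fig)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run the full flow and write the report bundle to ``outdir``.

    Returns a dict with the in-memory products (pairs, deltas, dcls,
    validation table, exclusion log, ...).  On any stage failure the
    partially written bundle is removed and the error re-raised with the
    stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "input"
    try:
        if config.generator is not None:
            pairs_raw = generate_cohort(config.generator)
            write_pairs(pairs_raw, outdir / "pairs.csv")
            raw = read_pairs(outdir / "pairs.csv")
        else:
            raw = read_pairs(config.input_csv)

        stage = "exclusions"
        pairs, excl_log = apply_exclusions(
            raw,
            min_interval_days=config.min_interval_days,
            max_interval_days=config.max_interval_days,
            min_age=config.min_age,
            min_group_n=config.min_group_n,
        )
        (outdir / "exclusions.json").write_text(excl_log.to_json())

        stage = "deltas"
        deltas = compute_deltas(pairs)

        stage = "split"
        split = split_dev_val(deltas, ratio=config.split_ratio,
                              seed=config.split_seed)
        dev = deltas.loc[split.dev_index()]
        val = deltas.loc[split.val_index()]

        stage = "estimation"
        dcls = estimate_dcls(dev, percentile=config.percentile,
                             metrics=config.metrics)
        if not dcls:
            raise ValueError("no stratum with enough data to estimate a limit")
        by_group = {}
        for d in dcls:
            by_group.setdefault((d.analyte, d.metric), {})[d.group] = d
        combined = [
            combine_dcls(g["IE"], g["O"])
            for g in by_group.values() if {"IE", "O"} <= g.keys()
        ]
        all_dcls = dcls + combined
        (outdir / "dcls.json").write_text(
            json.dumps([_dcl_record(d) for d in all_dcls], indent=2)
        )
        sex_table = sex_stratified_percentiles(dev)
        sex_table.to_csv(outdir / "sex_percentiles.tsv", sep="\t", index=False)

        stage = "validation"
        rows = []
        quantreg_rows = []
        for (analyte, metric), groups in sorted(by_group.items()):
            val_ie = val[(val["analyte"] == analyte) & (val["group"] == "IE")]
            val_o = val[(val["analyte"] == analyte) & (val["group"] == "O")]
            reports = []
            if "own" in config.validation_modes or \
               "cross" in config.validation_modes:
                reports += cross_validate(
                    {g: d for g, d in groups.items()},
                    val_ie if len(val_ie) else None,
                    val_o if len(val_o) else None,
                )
                if "cross" not in config.validation_modes:
                    reports = [r for r in reports if r.dcl_source == r.applied_to]
                elif "own" not in config.validation_modes:
                    reports = [r for r in reports if r.dcl_source != r.applied_to]
            comb = next((c for c in combined
                         if (c.analyte, c.metric) == (analyte, metric)), None)
            chisq = None
            if "combined" in config.validation_modes and comb is not None \
                    and len(val_ie) and len(val_o):
                rep_ie = proportion_outside(val_ie, comb, applied_to="IE")
                rep_o = proportion_outside(val_o, comb, applied_to="O")
                reports += [rep_ie, rep_o]
                chisq = chisq_compare(rep_ie, rep_o,
                                      correction=config.chisq_correction)
            for r in reports:
                rows.append({
                    "analyte": r.analyte, "metric": r.metric,
                    "dcl_source": r.dcl_source, "applied_to": r.applied_to,
                    "limit": r.limit, "n_val": r.n_val,
                    "n_outside": r.n_outside,
                    "proportion_outside": round(r.proportion_outside, 1),
                    "chisq_p": (chisq.p_value
                                if chisq is not None and r.dcl_source == "combined"
                                else float("nan")),
                })
            if config.quantreg and "IE" in groups and "O" in groups:
                dev_ie = dev[(dev["analyte"] == analyte) & (dev["group"] == "IE")]
                dev_o = dev[(dev["analyte"] == analyte) & (dev["group"] == "O")]
                qr = quantreg_group_test(
                    dev_ie, dev_o, metric=metric,
                    tau=config.percentile / 100.0,
                    n_boot=config.n_boot, seed=config.bootstrap_seed,
                    analyte=analyte,
                )
                quantreg_rows.append({
                    "analyte": analyte, "metric": metric, "tau": qr.tau,
                    "intercept": qr.intercept, "coef_group": qr.coef_group,
                    "p_value": qr.p_value, "n_boot": qr.n_boot,
                })
        validation = pd.DataFrame(rows)
        validation.to_csv(outdir / "validation.tsv", sep="\t", index=False)
        quantreg_df = pd.DataFrame(quantreg_rows)
        if len(quantreg_df):
            quantreg_df.to_csv(outdir / "quantreg.tsv", sep="\t", index=False)

        stage = "rcv"
        rcvs, skipped = rcv_table(list(config.bio_variation))
        rcv_df = pd.DataFrame([
            {"analyte": r.analyte, "z": r.z, "decrease": r.decrease,
             "increase": r.increase,
             "decrease_ci_low": r.decrease_ci[0] if r.decrease_ci else float("nan"),
             "decrease_ci_high": r.decrease_ci[1] if r.decrease_ci else float("nan"),
             "increase_ci_low": r.increase_ci[0] if r.increase_ci else float("nan"),
             "increase_ci_high": r.increase_ci[1] if r.increase_ci else float("nan")}
            for r in rcvs
        ])
        rcv_df.to_csv(outdir / "rcv.tsv", sep="\t", index=False)

        stage = "plots"
        if config.make_plots:
            _plot_distributions(deltas, all_dcls, outdir / "plots")

        stage = "manifest"
        manifest = {
            "deltacheck_version": __version__,
            "config": json.loads(config.to_json()),
            "seeds": {"split": config.split_seed,
                      "bootstrap": config.bootstrap_seed,
                      "generator": (config.generator.seed
                                    if config.generator else None)},
            "n_retained": int(excl_log.retained),
            "rcv_skipped_no_cvi": skipped,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as err:
        shutil.rmtree(outdir, ignore_errors=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}") from err

    return {
        "pairs": pairs, "deltas": deltas, "dev": dev, "val": val,
        "dcls": all_dcls, "validation": validation, "quantreg": quantreg_df,
        "sex_percentiles": sex_table, "rcv": rcv_df,
        "exclusion_log": excl_log,
    }
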
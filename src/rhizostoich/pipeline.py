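"""End-to-end orchestration: simulate -> analyze -> report.

``run_analyze`` reads (or receives) a validated dataset and writes the
full output bundle as CSVs in a stable order, each file carrying a
``#``-prefixed first line with the config hash and package version so a
bundle is self-identifying.  Any stage failure aborts the run, removes
partial outputs, and re-raises with the stage name.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_model import Dataset, SOIL_VARS
from .errors import RhizostoichError, ConfigError, DataValidationError
from .io import read_dataset, validate_dataset
from .rhizosphere import re_profiles, summarize_re, RE_VARS
from .stats import (
    ALPHA_DEFAULT,
    lsd_pairwise,
    pearson_matrix,
    significance_stars,
    trend_fit,
    two_way_anova,
)
from .vectors import (
    ROOT_ANGLE_HIGH,
    ROOT_ANGLE_LOW,
    plot_vector_metrics,
    sma_fit,
)

log = logging.getLogger("rhizostoich")

#: bundle files in write order
BUNDLE_FILES = (
    "re_profiles.csv",
    "re_summary.csv",
    "vector_metrics.csv",
    "sma_fits.csv",
    "anova_tables.csv",
    "lsd_letters.csv",
    "correlations.csv",
    "trend_fits.csv",
    "limitation_summary.csv",
    "run_log.json",
)

#: responses entering the two-way ANOVA, mirroring the root-property,
#: microbe-property and rhizosphere-effect blocks of the field analysis
ANOVA_RESPONSES = (
    "root_tc", "root_tn", "root_tp", "np_con", "root_vector_angle",
    "vector_length", "vector_angle", "np_see", "microbial_n_limitation",
) + RE_VARS

SMA_PAIRS = (
    ("C:N", "ln_bg", "ln_n_acq"),
    ("C:P", "ln_bg", "ln_acp"),
    ("N:P", "ln_n_acq", "ln_acp"),
)


@dataclass
class RunConfig:
    """Everything one analysis run needs; hashable for provenance."""

    input_path: str | None = None
    schema: dict | None = None
    out_dir: str = "results"
    thresholds: tuple = (ROOT_ANGLE_LOW, ROOT_ANGLE_HIGH)
    microbial_threshold: float = 45.0
    alpha: float = ALPHA_DEFAULT
    sma_grouping: str = "age"        # "age" or "pooled"
    seed: int = 0
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        low, high = self.thresholds
        if not (0 < low < high):
            raise ConfigError(f"thresholds must be ordered positive, got {self.thresholds}")
        if not (0 < self.alpha < 1):
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")

    def config_hash(self) -> str:
        # hash only analysis-relevant settings: where the bundle lands and
        # how loudly we log must not change its identity
        payload = {
            k: v for k, v in self.__dict__.items()
            if k not in ("extra", "out_dir", "log_level")
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, comment: str) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# {comment}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def run_analyze(cfg: RunConfig, dataset: Dataset | None = None) -> dict:
    """Run every analysis stage and write the output bundle.

    Returns {file name: DataFrame} for the tabular outputs.  Stages run in
    a fixed order; on failure all partial outputs are removed and the
    error is re-raised naming the stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    comment = f"rhizostoich {__version__} config {cfg.config_hash()}"
    written: list[Path] = []
    produced: dict = {}

    stage = "load"
    try:
        ds = dataset if dataset is not None else read_dataset(cfg.input_path, cfg.schema)
        stage = "validate"
        report = validate_dataset(ds)
        if report.fatal:
            raise DataValidationError(report.fatal)
        if not report.log_domain_ok:
            raise DataValidationError(report.rules["enzyme_log_domain"][1])

        for stage, builder in (
            ("rhizosphere_effects", _stage_re),
            ("vector_metrics", _stage_vectors),
            ("sma_fits", _stage_sma),
            ("anova", _stage_anova),
            ("correlations", _stage_correlations),
            ("trend_fits", _stage_trends),
            ("limitation_summary", _stage_limitation),
        ):
            for fname, df in builder(ds, cfg, produced).items():
                path = out / fname
                _write_csv(df, path, comment)
                written.append(path)
                produced[fname] = df
                log.info("wrote %s (%d rows)", path, len(df))

        stage = "run_log"
        run_log = {
            "package_version": __version__,
            "config_hash": cfg.config_hash(),
            "n_observations": len(ds),
            "balanced": ds.is_balanced,
            "files": [p.name for p in written],
        }
        (out / "run_log.json").write_text(json.dumps(run_log, indent=2))
        written.append(out / "run_log.json")
    except Exception as e:
        for p in written:
            p.unlink(missing_ok=True)
        raise RhizostoichError(f"stage '{stage}' failed: {e}") from e
    return produced


def _stage_re(ds, cfg, produced):
    profiles = re_profiles(ds)
    per_plot = pd.DataFrame([p.as_dict() for p in profiles])
    summary = summarize_re(profiles, by=("age_class", "n_level"))
    return {"re_profiles.csv": per_plot, "re_summary.csv": summary}


def _stage_vectors(ds, cfg, produced):
    rows = [plot_vector_metrics(obs, cfg.thresholds) for obs in ds]
    return {"vector_metrics.csv": pd.DataFrame(rows)}


def _stage_sma(ds, cfg, produced):
    vm = produced["vector_metrics.csv"]
    lnvals = pd.DataFrame({
        "age_class": vm["age_class"],
        "ln_bg": np.log([obs.rhizo_enzymes.bg for obs in ds]),
        "ln_n_acq": np.log([obs.rhizo_enzymes.n_acq for obs in ds]),
        "ln_acp": np.log([obs.rhizo_enzymes.acp for obs in ds]),
    })
    groups = (
        [("pooled", lnvals)] if cfg.sma_grouping == "pooled"
        else [(str(a), g) for a, g in lnvals.groupby("age_class")]
    )
    rows = []
    for gname, g in groups:
        for pair, xcol, ycol in SMA_PAIRS:
            fit = sma_fit(g[xcol], g[ycol])
            rows.append({
                "group": gname, "pairing": pair, "x": xcol, "y": ycol,
                "slope": fit.slope, "intercept": fit.intercept,
                "r": fit.r, "n": fit.n,
            })
    return {"sma_fits.csv": pd.DataFrame(rows)}


def _response_frame(ds, produced) -> pd.DataFrame:
    vm = produced["vector_metrics.csv"]
    rp = produced["re_profiles.csv"]
    df = vm.merge(rp, on=["age_class", "n_level", "block"], validate="1:1")
    df["root_tc"] = [obs.root.tc for obs in ds]
    df["root_tn"] = [obs.root.tn for obs in ds]
    df["root_tp"] = [obs.root.tp for obs in ds]
    return df


def _stage_anova(ds, cfg, produced):
    df = _response_frame(ds, produced)
    anova_rows, letter_rows = [], []
    for resp in ANOVA_RESPONSES:
        table = two_way_anova(df[resp], df["age_class"], df["n_level"],
                              names=("age", "n_level"))
        for term, vals in table.terms.items():
            anova_rows.append({
                "response": resp, "term": term, **vals,
                "stars": significance_stars(vals["p"]),
            })
        letter_rows += _lsd_letters_for(df, resp, cfg.alpha)
    return {
        "anova_tables.csv": pd.DataFrame(anova_rows),
        "lsd_letters.csv": pd.DataFrame(letter_rows),
    }


def _one_way_mse(values: pd.Series, labels: pd.Series):
    groups = values.groupby(labels)
    means = groups.mean()
    counts = groups.count()
    ss_e = float(((values - labels.map(means)) ** 2).sum())
    df_e = int(len(values) - len(means))
    return means.to_dict(), counts.to_dict(), ss_e / df_e if df_e else np.nan, df_e


def _lsd_letters_for(df, resp, alpha):
    rows = []
    # small letters: N levels within each age class
    for age, g in df.groupby("age_class"):
        means, counts, mse, df_e = _one_way_mse(g[resp], g["n_level"])
        if df_e < 1 or not np.isfinite(mse) or mse <= 0:
            continue
        disp = lsd_pairwise(means, counts, mse, df_e, alpha)
        for grp, letter in disp.letters.items():
            rows.append({"response": resp, "comparison": "n_level_within_age",
                         "age_class": age, "group": grp,
                         "mean": disp.means[grp], "letters": letter})
    # capital letters: age classes pooled over N levels
    means, counts, mse, df_e = _one_way_mse(df[resp], df["age_class"])
    if df_e >= 1 and np.isfinite(mse) and mse > 0:
        disp = lsd_pairwise(means, counts, mse, df_e, alpha)
        for grp, letter in disp.letters.items():
            rows.append({"response": resp, "comparison": "age_class",
                         "age_class": grp, "group": grp,
                         "mean": disp.means[grp], "letters": letter.upper()})
    return rows


def _stage_correlations(ds, cfg, produced):
    df = _response_frame(ds, produced)
    cols = list(RE_VARS) + ["root_tc", "root_tn", "root_tp", "np_con",
                            "root_vector_angle", "microbial_n_limitation"]
    r_mat, p_mat = pearson_matrix(df[cols])
    rows = []
    for i, c1 in enumerate(cols):
        for c2 in cols[i + 1:]:
            p = p_mat.loc[c1, c2]
            rows.append({"var1": c1, "var2": c2, "r": r_mat.loc[c1, c2],
                         "p": p, "stars": significance_stars(p)})
    return {"correlations.csv": pd.DataFrame(rows)}


def _stage_trends(ds, cfg, produced):
    rp = produced["re_profiles.csv"]
    n_order = {nl: i for i, nl in enumerate(ds.n_levels)}
    rows = []
    for age, g in rp.groupby("age_class"):
        x = g["n_level"].map(n_order).to_numpy(float)
        for var in RE_VARS:
            for order in (1, 2):
                fit = trend_fit(x, g[var].to_numpy(float), order=order)
                coefs = list(fit.coefficients) + [np.nan] * (3 - len(fit.coefficients))
                rows.append({
                    "age_class": age, "response": var, "order": order,
                    "intercept": coefs[0], "linear": coefs[1],
                    "quadratic": coefs[2], "r_squared": fit.r_squared,
                    "p": fit.p_value, "stars": significance_stars(fit.p_value),
                })
    return {"trend_fits.csv": pd.DataFrame(rows)}


def _stage_limitation(ds, cfg, produced):
    vm = produced["vector_metrics.csv"]
    rows = []
    for (age, nl), g in vm.groupby(["age_class", "n_level"]):
        row = {"age_class": age, "n_level": nl, "n_plots": len(g)}
        for kind in ("microbial_call", "root_call"):
            counts = g[kind].value_counts()
            for call in ("N-limited", "P-limited", "balanced", "unlimited"):
                row[f"{kind}_{call}"] = int(counts.get(call, 0))
        rows.append(row)
    return {"limitation_summary.csv": pd.DataFrame(rows)}


def run_report(bundle_dir) -> str:
    """Human-readable markdown summary of a completed output bundle."""
    bundle = Path(bundle_dir)
    missing = [f for f in BUNDLE_FILES if not (bundle / f).exists()]
    if missing:
        raise RhizostoichError(f"incomplete bundle, missing: {', '.join(missing)}")
    lim = pd.read_csv(bundle / "limitation_summary.csv", comment="#")
    anova = pd.read_csv(bundle / "anova_tables.csv", comment="#")
    corr = pd.read_csv(bundle / "correlations.csv", comment="#")

    lines = ["# Analysis report", ""]
    lines.append("## Nutrient-limitation calls per age x N cell")
    lines.append(lim.to_string(index=False))
    lines.append("")
    sig = anova[(anova["term"] != "Residual") & (anova["p"] < 0.05)]
    lines.append("## Significant ANOVA terms (alpha = 0.05)")
    if len(sig):
        for _, row in sig.iterrows():
            lines.append(
                f"- {row['response']}: {row['term']} "
                f"F = {row['F']:.3g}, p = {row['p']:.3g} {row['stars']}"
            )
    else:
        lines.append("no significant terms at alpha = 0.05")
    lines.append("")
    lines.append("## Strongest correlations")
    top = corr.reindex(corr["r"].abs().sort_values(ascending=False).index).head(10)
    for _, row in top.iterrows():
        lines.append(
            f"- {row['var1']} ~ {row['var2']}: r = {row['r']:.3f} {row['stars']}"
        )
    return "\n".join(lines) + "\n"
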
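"""CSV readers/writers and dataset validation.

Two tabular layouts are accepted:

* **wide** -- one row per plot; paired soil columns carry ``rhizo_`` /
  ``bulk_`` prefixes (``rhizo_soc``, ``bulk_soc``, ...); enzyme and root
  columns are unprefixed (``bg``, ``nag``, ``lap``, ``acp``, ``root_tc``...).
* **long** -- two rows per plot distinguished by a ``compartment`` column
  (``rhizosphere`` / ``bulk``); enzyme and root values are read from the
  rhizosphere row.

A schema dict may remap any column name; units are declared, not inferred.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field

import pandas as pd

from .data_model import (
    DEFAULT_AGE_LEVELS,
    DEFAULT_N_LEVELS,
    Dataset,
    DesignKey,
    EnzymeProfile,
    PlotObservation,
    RootChemistry,
    SoilChemistry,
    SOIL_VARS,
)
from .errors import ContractError, DataValidationError, PairingError, SchemaError

KEY_COLS = ("age_class", "n_level", "block", "plot")
ENZ_COLS = ("bg", "nag", "lap", "acp")
ROOT_COLS = ("root_tc", "root_tn", "root_tp")


def _required_columns(fmt: str) -> list[str]:
    cols = ["age_class", "n_level", "block"]
    if fmt == "wide":
        cols += [f"rhizo_{v}" for v in SOIL_VARS]
        cols += [f"bulk_{v}" for v in SOIL_VARS]
    else:
        cols += ["compartment"]
        cols += list(SOIL_VARS)
    cols += list(ENZ_COLS) + list(ROOT_COLS)
    return cols


def _apply_schema(df: pd.DataFrame, schema: dict | None) -> pd.DataFrame:
    if schema and "columns" in schema:
        # schema maps canonical field -> CSV column name
        rename = {v: k for k, v in schema["columns"].items()}
        df = df.rename(columns=rename)
    return df


def _numeric(row, col, idx):
    v = row[col]
    try:
        x = float(v)
    except (TypeError, ValueError):
        raise DataValidationError(f"row {idx}: column {col!r} is not numeric: {v!r}")
    if not x > 0:
        raise DataValidationError(
            f"row {idx}: column {col!r} must be > 0 (ratio/percent-difference "
            f"denominators require positive concentrations), got {x}"
        )
    return x


def read_dataset(path, schema: dict | None = None) -> Dataset:
    """Read a wide- or long-format CSV into a validated :class:`Dataset`.

    ``schema`` may carry ``format`` (``"wide"``/``"long"``; auto-detected
    from the presence of a ``compartment`` column when absent), a
    ``columns`` mapping of canonical field name to CSV column name, and
    ``age_levels`` / ``n_levels`` overrides.
    """
    df = pd.read_csv(path, comment="#")
    df = _apply_schema(df, schema)
    fmt = (schema or {}).get("format")
    if fmt is None:
        fmt = "long" if "compartment" in df.columns else "wide"
    missing = [c for c in _required_columns(fmt) if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    age_levels = tuple((schema or {}).get("age_levels", DEFAULT_AGE_LEVELS))
    n_levels = tuple((schema or {}).get("n_levels", DEFAULT_N_LEVELS))

    if fmt == "long":
        df = _long_to_wide(df)

    observations = []
    for idx, row in df.iterrows():
        key = DesignKey(
            age_class=int(row["age_class"]),
            n_level=str(row["n_level"]),
            block=str(row["block"]),
            plot=str(row.get("plot", "")),
        )
        rhizo = SoilChemistry(**{v: _numeric(row, f"rhizo_{v}", idx) for v in SOIL_VARS})
        bulk = SoilChemistry(**{v: _numeric(row, f"bulk_{v}", idx) for v in SOIL_VARS})
        enz = EnzymeProfile(**{c: _numeric(row, c, idx) for c in ENZ_COLS})
        root = RootChemistry(
            tc=_numeric(row, "root_tc", idx),
            tn=_numeric(row, "root_tn", idx),
            tp=_numeric(row, "root_tp", idx),
        )
        observations.append(PlotObservation(key, rhizo, bulk, enz, root))
    return Dataset(observations, age_levels=age_levels, n_levels=n_levels)


def _long_to_wide(df: pd.DataFrame) -> pd.DataFrame:
    keys = ["age_class", "n_level", "block"]
    if "plot" in df.columns:
        keys.append("plot")
    rows = []
    for key_vals, grp in df.groupby(keys, sort=False):
        comps = set(grp["compartment"].str.lower())
        keyrepr = dict(zip(keys, key_vals if isinstance(key_vals, tuple) else (key_vals,)))
        for want in ("rhizosphere", "bulk"):
            if want not in comps:
                raise PairingError(
                    f"plot {keyrepr} lacks its {want} compartment row"
                )
        rhizo = grp[grp["compartment"].str.lower() == "rhizosphere"].iloc[0]
        bulk = grp[grp["compartment"].str.lower() == "bulk"].iloc[0]
        row = dict(keyrepr)
        row.setdefault("plot", "")
        for v in SOIL_VARS:
            row[f"rhizo_{v}"] = rhizo[v]
            row[f"bulk_{v}"] = bulk[v]
        for c in ENZ_COLS + ROOT_COLS:
            row[c] = rhizo[c]
        rows.append(row)
    return pd.DataFrame(rows)


def dataset_to_frame(ds: Dataset) -> pd.DataFrame:
    """Wide-format DataFrame view of a dataset (column order stable)."""
    rows = []
    for obs in ds:
        row = {
            "age_class": obs.key.age_class,
            "n_level": obs.key.n_level,
            "block": obs.key.block,
            "plot": obs.key.plot,
        }
        for v in SOIL_VARS:
            row[f"rhizo_{v}"] = getattr(obs.rhizo_soil, v)
        for v in SOIL_VARS:
            row[f"bulk_{v}"] = getattr(obs.bulk_soil, v)
        for c in ENZ_COLS:
            row[c] = getattr(obs.rhizo_enzymes, c)
        row["root_tc"] = obs.root.tc
        row["root_tn"] = obs.root.tn
        row["root_tp"] = obs.root.tp
        rows.append(row)
    return pd.DataFrame(rows)


def write_dataset(ds: Dataset, path) -> None:
    """Write the wide-format CSV for a dataset at full float precision."""
    dataset_to_frame(ds).to_csv(path, index=False, float_format="%.17g")


def write_table(rows: list[dict], path, display_round: int | None = None) -> None:
    """Write result records to CSV with a stable column order.

    All records must share one header (first record's key order wins).
    Floats are written at full precision; with ``display_round`` set, each
    float column gains a rounded ``<name>_disp`` companion for human
    reading.  An empty record list writes a header-only (empty) CSV.
    """
    header = list(rows[0].keys()) if rows else []
    for i, r in enumerate(rows[1:], start=1):
        if list(r.keys()) != header:
            raise ContractError(
                f"record {i} header {list(r.keys())} differs from {header}"
            )
    float_cols = {h for h in header if isinstance(rows[0][h], float)}
    out_header = []
    for h in header:
        out_header.append(h)
        if display_round is not None and h in float_cols:
            out_header.append(f"{h}_disp")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(out_header)
        for r in rows:
            out = []
            for h in header:
                v = r[h]
                out.append(f"{v:.17g}" if isinstance(v, float) else v)
                if display_round is not None and h in float_cols:
                    out.append(round(float(v), display_round))
            w.writerow(out)


@dataclass
class ValidationReport:
    """Per-rule pass/fail plus replicate counts and log-domain status."""

    rules: dict = field(default_factory=dict)  # rule name -> (passed, detail)
    cell_counts: dict = field(default_factory=dict)
    log_domain_ok: bool = True
    fatal: str | None = None

    @property
    def all_passed(self) -> bool:
        return self.fatal is None and all(p for p, _ in self.rules.values())


def validate_dataset(ds) -> ValidationReport:
    """Report-only validation: key uniqueness, balance, positivity and the
    enzyme log-domain rule (BG, NAG+LAP, ACP all > 1 nmol g-1 h-1)."""
    report = ValidationReport()
    if ds is None or len(ds) == 0:
        report.fatal = "no observations"
        return report
    report.cell_counts = ds.cell_counts()
    report.rules["key_uniqueness"] = (True, "enforced at construction")
    report.rules["positivity"] = (True, "enforced at construction")
    balanced = ds.is_balanced
    report.rules["balanced_design"] = (
        balanced,
        "every age x N cell has equal replicates" if balanced
        else f"unequal cell counts: {sorted(set(report.cell_counts.values()))}",
    )
    bad = [
        (obs.key.age_class, obs.key.n_level, obs.key.block)
        for obs in ds
        if not obs.rhizo_enzymes.log_domain_ok()
    ]
    report.log_domain_ok = not bad
    report.rules["enzyme_log_domain"] = (
        not bad,
        "all BG, NAG+LAP, ACP > 1 nmol g-1 h-1" if not bad
        else f"activities <= 1 nmol g-1 h-1 (ln <= 0) in plots {bad}; "
             "vector analysis would be undefined",
    )
    return report
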
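"""Rhizosphere effects: percent difference between paired rhizospheric
and non-rhizospheric (bulk) soil.

RE = (C_R - C_N) / C_N * 100

where C_R and C_N are the concentrations of a soil variable in the
rhizospheric and the bulk compartment of the same plot.  Positive values
mean enrichment near roots.  REs are computed per observation and then
summarized; they are never computed from group-mean concentrations,
which would break the within-plot pairing.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import Dataset, DesignKey, PlotObservation, SOIL_VARS
from .errors import DomainError

RE_VARS = tuple(f"re_{v}" for v in SOIL_VARS)


def compute_re(c_r: float, c_n: float) -> float:
    """Percent rhizosphere effect for one paired measurement.

    Parameters
    ----------
    c_r, c_n
        Rhizospheric and bulk concentration in the same units.

    Returns
    -------
    float
        ``(c_r - c_n) / c_n * 100``; bounded below by -100 when c_r >= 0.
    """
    if not np.isfinite(c_n) or c_n <= 0:
        raise DomainError(f"bulk concentration must be > 0, got {c_n}")
    if not np.isfinite(c_r) or c_r < 0:
        raise DomainError(f"rhizosphere concentration must be >= 0, got {c_r}")
    return (c_r - c_n) / c_n * 100.0


@dataclass(frozen=True)
class REProfile:
    """Per-plot rhizosphere effects for the six soil indicators (percent)."""

    key: DesignKey
    re_soc: float
    re_tn: float
    re_tp: float
    re_nh4: float
    re_no3: float
    re_ap: float

    def as_dict(self) -> dict:
        d = {
            "age_class": self.key.age_class,
            "n_level": self.key.n_level,
            "block": self.key.block,
        }
        for v in RE_VARS:
            d[v] = getattr(self, v)
        return d


def re_profile(obs: PlotObservation) -> REProfile:
    """Rhizosphere effects of SOC, TN, TP, NH4+-N, NO3--N and AP for one plot."""
    values = {}
    for v in SOIL_VARS:
        try:
            values[f"re_{v}"] = compute_re(
                getattr(obs.rhizo_soil, v), getattr(obs.bulk_soil, v)
            )
        except DomainError as e:
            raise DomainError(f"{v.upper()}: {e}") from e
    return REProfile(key=obs.key, **values)


def re_profiles(ds: Dataset) -> list[REProfile]:
    return [re_profile(obs) for obs in ds]


def summarize_re(profiles: list[REProfile], by=("age_class",)) -> pd.DataFrame:
    """Group means, standard deviations and n for each RE variable.

    ``by`` is any subset of {"age_class", "n_level", "block"}.  Empty
    groups cannot arise from grouping existing profiles; groups of size 1
    report sd = NaN with a warning.
    """
    if not profiles:
        warnings.warn("summarize_re called with no profiles; empty summary")
        return pd.DataFrame()
    df = pd.DataFrame([p.as_dict() for p in profiles])
    by = list(by)
    grouped = df.groupby(by, sort=True)[list(RE_VARS)]
    out = grouped.agg(["mean", "std", "count"])
    out.columns = [f"{var}_{stat}" for var, stat in out.columns]
    if (grouped.count().min(axis=None)) < 2:
        warnings.warn("some groups have a single profile; sd is undefined there")
    return out.reset_index()
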
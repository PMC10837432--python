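"""Pulse-chase experiment data model and analysis stages.

The experiment: sponges sit in labelled water for a 3 h pulse, are rinsed
for 1 h, then share tanks with coral fragments for a 6 h chase during
which corals and their Symbiodiniaceae can take up sponge-released
tracer.  Destructive sampling happens at hour 0 (T0), hour 3 (sponge
pulse point only), hour 7 (T3, mid-chase) and hour 10 (T6, end of
chase), so T3/T6 fragments were exposed to labelled water for 3 and 6
chase-hours respectively.

This module turns a table of bulk measurements (delta13C, delta15N, %C,
%N, dry mass per specimen) into baselines, per-sample excess
incorporation and incorporation rates, boxplot-style group summaries,
holobiont (host + symbiont) totals and the 15N:13C fold-ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import tracer
from .constants import DEFAULT_REGISTRY, ConstantsRegistry, ELEMENTS

__all__ = [
    "ExperimentDesign",
    "SAMPLE_COLUMNS",
    "validate_samples",
    "compute_baselines",
    "compute_incorporation_table",
    "summarize_groups",
    "fold_ratio_n_vs_c",
    "assemble_holobiont_totals",
]

TIMEPOINTS = ("T0", "PULSE", "T3", "T6")
FRACTIONS = ("sponge_tissue", "coral_host", "symbiodiniaceae")
ORGANISMS = ("sponge", "coral")
TREATMENTS = ("enriched", "control")

#: canonical column order of a bulk-sample table
SAMPLE_COLUMNS = [
    "sample_id", "organism", "species", "fraction", "treatment",
    "timepoint", "tank_id", "delta13C", "delta15N", "pctC", "pctN",
    "dry_mass_mg",
]

_DELTA_COL = {"C": "delta13C", "N": "delta15N"}
_PCT_COL = {"C": "pctC", "N": "pctN"}


@dataclass(frozen=True)
class ExperimentDesign:
    """Timeline of the pulse-chase experiment (hours)."""

    pulse_h: float = 3.0
    rinse_h: float = 1.0
    chase_h: float = 6.0

    @property
    def timepoint_hours(self) -> Mapping[str, float]:
        return {
            "T0": 0.0,
            "PULSE": self.pulse_h,
            "T3": self.pulse_h + self.rinse_h + self.chase_h / 2.0,
            "T6": self.pulse_h + self.rinse_h + self.chase_h,
        }

    @property
    def chase_exposure_hours(self) -> Mapping[str, float]:
        """Hours of exposure to labelled water for each chase timepoint."""
        start = self.pulse_h + self.rinse_h
        return {tp: h - start for tp, h in self.timepoint_hours.items()
                if tp in ("T3", "T6")}


def validate_samples(df: pd.DataFrame):
    """Split a sample table into valid rows and rejected rows.

    Returns ``(clean, rejects)``; ``rejects`` carries a ``reason`` column
    and the original (0-based) row index in ``row``.  Checks both field
    domains and the design invariants: sponges carry only the
    sponge_tissue fraction, the PULSE timepoint exists for sponges only,
    and the control treatment exists for corals only (control tanks held
    no sponges).
    """
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    df = df[SAMPLE_COLUMNS].copy()

    reasons = []
    for idx, r in df.iterrows():
        why = None
        if r.organism not in ORGANISMS:
            why = f"unknown organism {r.organism!r}"
        elif r.fraction not in FRACTIONS:
            why = f"unknown fraction {r.fraction!r}"
        elif r.treatment not in TREATMENTS:
            why = f"unknown treatment {r.treatment!r}"
        elif r.timepoint not in TIMEPOINTS:
            why = f"unknown timepoint {r.timepoint!r}"
        elif r.organism == "sponge" and r.fraction != "sponge_tissue":
            why = "sponge rows must have fraction 'sponge_tissue'"
        elif r.organism == "coral" and r.fraction == "sponge_tissue":
            why = "coral rows need a coral_host/symbiodiniaceae fraction"
        elif r.timepoint == "PULSE" and r.organism != "sponge":
            why = "PULSE timepoint exists for sponges only"
        elif r.treatment == "control" and r.organism != "coral":
            why = "control treatment exists for corals only"
        elif not np.isfinite(r.delta13C) or r.delta13C <= -1000:
            why = "delta13C must be finite and > -1000 permil"
        elif not np.isfinite(r.delta15N) or r.delta15N <= -1000:
            why = "delta15N must be finite and > -1000 permil"
        elif not (0 < r.pctC <= 100) or not (0 < r.pctN <= 100):
            why = "pctC/pctN must lie in (0, 100]"
        elif not r.dry_mass_mg > 0:
            why = "dry_mass_mg must be > 0"
        reasons.append(why)

    reason_s = pd.Series(reasons, index=df.index)
    bad = reason_s.notna()
    rejects = df[bad].copy()
    rejects["reason"] = reason_s[bad]
    rejects["row"] = rejects.index
    return df[~bad].reset_index(drop=True), rejects.reset_index(drop=True)


def _sample_atom_fractions(df, element, registry):
    std = registry.standard(element)
    return tracer.delta_to_atom_fraction(df[_DELTA_COL[element]].to_numpy(), std)


def _sample_umol(df, element, registry):
    return tracer.element_micromoles(
        df[_PCT_COL[element]].to_numpy(), df["dry_mass_mg"].to_numpy(),
        registry.element(element))


def compute_baselines(samples: pd.DataFrame, policy: str = "t0_mean",
                      registry: ConstantsRegistry = DEFAULT_REGISTRY) -> pd.DataFrame:
    """Background atom fractions and elemental pools per species x fraction.

    ``t0_mean`` averages the treatment-agnostic T0 samples of each species
    x fraction (the only option for sponges, which have no controls);
    ``time_matched_control`` averages the control samples of the same
    timepoint, yielding one baseline row per species x fraction x
    timepoint (corals only).  Averaging happens in atom-fraction space;
    the tabulated delta is the delta of the mean atom fraction.
    """
    if policy not in ("t0_mean", "time_matched_control"):
        raise ValueError(f"unknown baseline policy {policy!r}")

    if policy == "t0_mean":
        base = samples[samples.timepoint == "T0"]
        group_cols = ["species", "fraction"]
    else:
        base = samples[(samples.treatment == "control")
                       & samples.timepoint.isin(["T3", "T6"])]
        group_cols = ["species", "fraction", "timepoint"]
    if base.empty:
        raise ValueError(f"no baseline samples available under policy {policy!r}")

    rows = []
    for key, grp in base.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        for el in ELEMENTS:
            f = _sample_atom_fractions(grp, el, registry)
            umol = _sample_umol(grp, el, registry)
            mean_f = float(np.mean(f))
            rows.append({
                "species": key[0],
                "fraction": key[1],
                "timepoint": key[2] if policy == "time_matched_control" else None,
                "element": el,
                "atom_fraction": mean_f,
                "delta": tracer.atom_fraction_to_delta(mean_f, registry.standard(el)),
                "element_umol": float(np.mean(umol)),
                "n": int(len(grp)),
                "policy": policy,
            })
    return pd.DataFrame(rows)


def _baseline_lookup(baselines: pd.DataFrame):
    policy = baselines["policy"].iloc[0]
    table = {}
    for r in baselines.itertuples(index=False):
        key = (r.species, r.fraction, r.element)
        if policy == "time_matched_control":
            key = key + (r.timepoint,)
        table[key] = r
    return policy, table


def compute_incorporation_table(samples: pd.DataFrame, baselines: pd.DataFrame,
                                design: ExperimentDesign = ExperimentDesign(),
                                registry: ConstantsRegistry = DEFAULT_REGISTRY,
                                treatments: Iterable[str] = ("enriched",)
                                ) -> pd.DataFrame:
    """Per-sample, per-element delta change, excess tracer and rate.

    One row per scored sample x element.  ``delta_change`` is the sample
    delta minus the baseline delta; ``excess_umol`` is the atom-fraction
    excess times the sample's elemental pool; ``rate`` (umol tracer per
    mmol of element in the initial sample per hour of chase exposure) is
    present only for chase timepoints T3/T6, with the initial-sample
    elemental pool taken from the baseline table.  By default only
    enriched samples are scored; pass ``treatments=("enriched",
    "control")`` to score controls against the same baselines.
    """
    policy, lookup = _baseline_lookup(baselines)
    scored = samples[samples.treatment.isin(tuple(treatments))]
    exposure = design.chase_exposure_hours

    rows = []
    for r in scored.itertuples(index=False):
        for el in ELEMENTS:
            key = (r.species, r.fraction, el)
            if policy == "time_matched_control":
                tp = r.timepoint if r.timepoint in ("T3", "T6") else None
                b = lookup.get(key + (tp,))
            else:
                b = lookup.get(key)
            if b is None:
                raise KeyError(
                    f"no baseline for (species={r.species!r}, "
                    f"fraction={r.fraction!r}, element={el!r}) under "
                    f"policy {policy!r} (sample {r.sample_id})")
            std = registry.standard(el)
            delta = getattr(r, _DELTA_COL[el])
            try:
                f_s = tracer.delta_to_atom_fraction(delta, std)
                umol = tracer.element_micromoles(
                    getattr(r, _PCT_COL[el]), r.dry_mass_mg, registry.element(el))
                excess = tracer.excess_incorporation(f_s, b.atom_fraction, umol)
            except ValueError as err:
                raise ValueError(f"sample {r.sample_id}: {err}") from err
            row = {
                "sample_id": r.sample_id,
                "organism": r.organism,
                "species": r.species,
                "fraction": r.fraction,
                "treatment": r.treatment,
                "timepoint": r.timepoint,
                "tank_id": r.tank_id,
                "element": el,
                "heavy_isotope": registry.element(el).heavy_isotope_label,
                "delta_change": delta - b.delta,
                "excess_umol": excess,
                "sample_element_umol": umol,
                "baseline_element_umol": b.element_umol,
                "exposure_h": np.nan,
                "rate": np.nan,
            }
            if r.timepoint in exposure:
                h = exposure[r.timepoint]
                row["exposure_h"] = h
                row["rate"] = tracer.incorporation_rate(
                    excess, b.element_umol / 1000.0, h)
            rows.append(row)
    return pd.DataFrame(rows)


def _quartile_summary(values: np.ndarray) -> dict:
    # linear-interpolation quartiles (mainstream boxplot convention)
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    outliers = values[(values < lo_fence) | (values > hi_fence)]
    return {
        "n": int(values.size),
        "mean": float(values.mean()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "n_outliers": int(outliers.size),
        "outliers": ";".join(repr(float(v)) for v in outliers),
    }


def summarize_groups(results: pd.DataFrame, value: str = "excess_umol",
                     by: Iterable[str] = ("species", "fraction", "timepoint",
                                          "element")) -> pd.DataFrame:
    """Boxplot-style summaries per group: n, mean, quartiles (linear
    interpolation), whiskers at the most extreme values within 1.5x IQR of
    the hinges, and the points beyond them as outliers."""
    by = list(by)
    rows = []
    for key, grp in results.dropna(subset=[value]).groupby(by, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        rec = dict(zip(by, key))
        rec.update(_quartile_summary(grp[value].to_numpy(dtype=float)))
        rows.append(rec)
    return pd.DataFrame(rows)


def fold_ratio_n_vs_c(results: pd.DataFrame, timepoint: str = "T6") -> pd.DataFrame:
    """Per-species holobiont 15N:13C fold-ratio of summed excess.

    For each coral species, sums excess tracer over the host and symbiont
    fractions at the end-of-chase timepoint and divides the 15N sum by the
    13C sum.  A zero or negative 13C denominator is flagged (``defined``
    False) rather than dropped.  The frame's ``attrs`` carry the min/max
    across species with a defined ratio.
    """
    sub = results[(results.timepoint == timepoint)
                  & (results.treatment == "enriched")
                  & results.fraction.isin(["coral_host", "symbiodiniaceae"])]
    rows = []
    for sp, grp in sub.groupby("species", sort=True):
        sums = grp.groupby("element")["excess_umol"].sum()
        if "C" not in sums.index or "N" not in sums.index:
            raise ValueError(f"species {sp!r}: both elements required")
        c, n = float(sums["C"]), float(sums["N"])
        defined = c > 0
        rows.append({
            "species": sp,
            "excess_15n_umol": n,
            "excess_13c_umol": c,
            "fold_ratio": n / c if c != 0 else np.nan,
            "defined": defined,
        })
    out = pd.DataFrame(rows)
    ok = out[out.defined]
    out.attrs["fold_ratio_min"] = float(ok.fold_ratio.min()) if len(ok) else np.nan
    out.attrs["fold_ratio_max"] = float(ok.fold_ratio.max()) if len(ok) else np.nan
    return out


def assemble_holobiont_totals(results: pd.DataFrame,
                              timepoint: str = "T6") -> pd.DataFrame:
    """Host + symbiont mean excess per coral species x element.

    Totals are sums of the two fraction group means at the end-of-chase
    timepoint; per-fraction n is attached as provenance, and species
    missing a fraction are flagged incomplete rather than dropped.
    """
    sub = results[(results.timepoint == timepoint)
                  & (results.treatment == "enriched")
                  & results.fraction.isin(["coral_host", "symbiodiniaceae"])]
    rows = []
    for (sp, el), grp in sub.groupby(["species", "element"], sort=True):
        means = grp.groupby("fraction")["excess_umol"].agg(["mean", "count"])
        host = means.loc["coral_host"] if "coral_host" in means.index else None
        symb = means.loc["symbiodiniaceae"] if "symbiodiniaceae" in means.index else None
        rows.append({
            "species": sp,
            "element": el,
            "host_mean_excess_umol": float(host["mean"]) if host is not None else np.nan,
            "symbiont_mean_excess_umol": float(symb["mean"]) if symb is not None else np.nan,
            "holobiont_total_umol": (
                float(host["mean"]) + float(symb["mean"])
                if host is not None and symb is not None else np.nan),
            "n_host": int(host["count"]) if host is not None else 0,
            "n_symbiont": int(symb["count"]) if symb is not None else 0,
            "complete": host is not None and symb is not None,
        })
    return pd.DataFrame(rows)
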
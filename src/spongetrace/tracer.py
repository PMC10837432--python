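"""Exact two-isotope tracer arithmetic.

Conversions among delta notation, heavy/light isotope ratio and heavy-atom
fraction, plus the excess-incorporation bookkeeping used to express
enrichment in micromoles of tracer:

* ``delta -> ratio``:      R = R_std * (1 + delta/1000)
* ``ratio -> atom frac``:  F = R / (1 + R)
* excess incorporation:    (F_sample - F_baseline) * total umol of element
* incorporation rate:      excess / baseline mmol / hours of exposure

All mole bookkeeping is done in atom-fraction space, never on raw delta
differences; delta differences are a separate, purely descriptive quantity.
Negative excess is legal (a net tracer loss) and is never clipped.

Every function accepts scalars or numpy arrays and returns the same shape.
"""

from __future__ import annotations

import numpy as np

from .constants import DEFAULT_REGISTRY, ConstantsRegistry, ElementConstants, IsotopeStandard

__all__ = [
    "delta_to_ratio",
    "ratio_to_atom_fraction",
    "atom_fraction_to_delta",
    "delta_to_atom_fraction",
    "element_micromoles",
    "excess_incorporation",
    "excess_from_deltas",
    "incorporation_rate",
    "molar_cn_ratio",
]


def _as_array(x):
    arr = np.asarray(x, dtype=float)
    return arr, (arr.ndim == 0)


def _restore(arr: np.ndarray, scalar: bool):
    return float(arr) if scalar else arr


def delta_to_ratio(delta, standard: IsotopeStandard):
    """Heavy/light isotope ratio from a per-mil delta value.

    Raises ``ValueError`` for delta <= -1000 (negative heavy-isotope
    abundance).  delta = 0 returns exactly the standard's ratio.
    """
    d, scalar = _as_array(delta)
    if np.any(~np.isfinite(d)) or np.any(d <= -1000.0):
        raise ValueError("delta must be finite and > -1000 permil")
    return _restore(standard.ratio * (1.0 + d / 1000.0), scalar)


def ratio_to_atom_fraction(ratio):
    """Heavy-atom fraction F = R/(1+R); monotone, maps [0, inf) -> [0, 1)."""
    r, scalar = _as_array(ratio)
    if np.any(~np.isfinite(r)) or np.any(r < 0):
        raise ValueError("isotope ratio must be finite and >= 0")
    return _restore(r / (1.0 + r), scalar)


def atom_fraction_to_delta(atom_fraction, standard: IsotopeStandard):
    """Per-mil delta from heavy-atom fraction (inverse conversion chain)."""
    f, scalar = _as_array(atom_fraction)
    if np.any(~np.isfinite(f)) or np.any(f < 0) or np.any(f >= 1):
        raise ValueError("atom fraction must lie in [0, 1)")
    ratio = f / (1.0 - f)
    return _restore((ratio / standard.ratio - 1.0) * 1000.0, scalar)


def delta_to_atom_fraction(delta, standard: IsotopeStandard):
    """Convenience composition of :func:`delta_to_ratio` and
    :func:`ratio_to_atom_fraction`."""
    return ratio_to_atom_fraction(delta_to_ratio(delta, standard))


def element_micromoles(pct_element, dry_mass_mg, constants: ElementConstants):
    """Micromoles of an element in a sample from mass percent and dry mass.

    umol = (pct/100 * dry_mass_mg) / atomic_mass * 1000
    (mg of element divided by g/mol gives mmol; x1000 gives umol).
    """
    p, ps = _as_array(pct_element)
    m, ms = _as_array(dry_mass_mg)
    if np.any(p <= 0) or np.any(p > 100):
        raise ValueError("pct_element must lie in (0, 100]")
    if np.any(m <= 0):
        raise ValueError("dry mass must be > 0 mg")
    out = (p / 100.0) * m / constants.atomic_mass * 1000.0
    return _restore(np.asarray(out, dtype=float), ps and ms)


def excess_incorporation(f_sample, f_baseline, total_umol_element):
    """Micromoles of heavy isotope above baseline.

    excess = (F_sample - F_baseline) * total umol of the element in the
    sample.  The result may be negative (net tracer loss); it is preserved
    as such.
    """
    fs, s1 = _as_array(f_sample)
    fb, s2 = _as_array(f_baseline)
    tot, s3 = _as_array(total_umol_element)
    for f in (fs, fb):
        if np.any(f < 0) or np.any(f >= 1):
            raise ValueError("atom fractions must lie in [0, 1)")
    if np.any(tot <= 0):
        raise ValueError("total umol of element must be > 0")
    return _restore((fs - fb) * tot, s1 and s2 and s3)


def excess_from_deltas(delta_sample, delta_baseline, total_umol_element,
                       standard: IsotopeStandard):
    """Excess incorporation straight from two delta values (full chain)."""
    return excess_incorporation(
        delta_to_atom_fraction(delta_sample, standard),
        delta_to_atom_fraction(delta_baseline, standard),
        total_umol_element,
    )


def incorporation_rate(excess_umol, baseline_element_mmol, exposure_h):
    """Incorporation rate in umol of tracer per mmol of element in the
    initial sample per hour of exposure.

    The denominator is the elemental pool of the *initial* (pre-exposure)
    sample; exposure is hours spent in labelled water.  Sign follows the
    excess.  ``exposure_h`` must be > 0 — samples taken before any exposure
    have no defined rate.
    """
    ex, s1 = _as_array(excess_umol)
    mmol, s2 = _as_array(baseline_element_mmol)
    h, s3 = _as_array(exposure_h)
    if np.any(mmol <= 0):
        raise ValueError("baseline element mmol must be > 0")
    if np.any(h <= 0):
        raise ValueError("exposure hours must be > 0")
    return _restore(ex / mmol / h, s1 and s2 and s3)


def molar_cn_ratio(pct_c, pct_n, registry: ConstantsRegistry = DEFAULT_REGISTRY):
    """Dimensionless molar C:N ratio from mass percents."""
    pc, s1 = _as_array(pct_c)
    pn, s2 = _as_array(pct_n)
    if np.any(pc <= 0) or np.any(pn <= 0):
        raise ValueError("pctC and pctN must be > 0")
    mc = registry.element("C").atomic_mass
    mn = registry.element("N").atomic_mass
    return _restore((pc / mc) / (pn / mn), s1 and s2)
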
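"""Occupancy-based equilibrium arithmetic for a single-copy simulation box.

One protein and one ligand copy in a periodic box of volume V define equal
total concentrations C = 1 / (N_A V).  For the 1:1 complex P + L <-> PL with
equal totals, the bound fraction f and dissociation constant Kd are linked by

    Kd = C (1 - f)^2 / f
    f  = [(2C + Kd) - sqrt((2C + Kd)^2 - 4 C^2)] / (2C)

(the smaller quadratic root; the other root exceeds 1).  A block bootstrap
over the state series provides an honest interval for Kd when only a handful
of binding/unbinding events were observed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.constants import Avogadro

from .states import BindingStateSeries, _frame_weights

NM3_TO_LITRE = 1e-24


@dataclass(frozen=True)
class EquilibriumResult:
    total_conc: float  # mol/l, equal for protein and ligand
    bound_fraction: float
    kd: float  # mol/l
    saturation: float | None = None  # f at a user-supplied experimental Kd


def box_concentration(box_volume_nm3: float, n_copies: int = 1) -> float:
    """Concentration (mol/l) of n_copies solute molecules in a box of nm^3."""
    if box_volume_nm3 <= 0:
        raise ValueError("box volume must be positive")
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    return n_copies / (Avogadro * box_volume_nm3 * NM3_TO_LITRE)


def kd_from_fraction(f: float, total_conc: float) -> float:
    """Dissociation constant (mol/l) from bound fraction at equal totals C."""
    if not 0.0 < f < 1.0:
        raise ValueError("bound fraction must lie strictly in (0, 1)")
    if total_conc <= 0:
        raise ValueError("concentration must be positive")
    return total_conc * (1.0 - f) ** 2 / f


def fraction_from_kd(kd: float, total_conc: float) -> float:
    """Bound fraction (saturation) at equal totals C for a given Kd."""
    if kd < 0:
        raise ValueError("Kd must be non-negative")
    if total_conc <= 0:
        raise ValueError("concentration must be positive")
    if kd == 0:
        return 1.0
    b = 2.0 * total_conc + kd
    disc = b * b - 4.0 * total_conc * total_conc
    return float((b - np.sqrt(disc)) / (2.0 * total_conc))


def mass_concentration(molar: float, molecular_weight: float) -> float:
    """mg/ml from mol/l and g/mol."""
    if molar <= 0 or molecular_weight <= 0:
        raise ValueError("molar concentration and molecular weight must be positive")
    return molar * molecular_weight  # (mol/l)(g/mol) = g/l = mg/ml


def kd_uncertainty(
    series_list: list[BindingStateSeries],
    total_conc: float,
    n_boot: int = 1000,
    block_ns: float = 100.0,
    seed: int | None = None,
    bound_states: frozenset[str] = frozenset({"specific"}),
) -> dict:
    """Block-bootstrap percentile interval (2.5-97.5%) for Kd.

    The pooled state series is chopped into contiguous blocks of ``block_ns``
    (default 100 ns — longer than typical nonspecific dwells, so within-block
    autocorrelation is preserved); blocks are resampled with replacement, the
    time-weighted bound fraction of each resample is converted to Kd, and
    percentiles are taken.  Resamples with fraction exactly 0 or 1 cannot be
    converted and are skipped (their count is reported).
    """
    if not series_list:
        raise ValueError("need at least one series")
    rng = np.random.default_rng(seed)
    block_w: list[float] = []
    block_bound: list[float] = []
    for series in series_list:
        w = _frame_weights(series.times)
        bound = np.isin(series.state, list(bound_states)).astype(float)
        edges = np.arange(series.times[0], series.times[-1] + block_ns, block_ns)
        which = np.clip(np.digitize(series.times, edges) - 1, 0, len(edges) - 2)
        for b in range(len(edges) - 1):
            mask = which == b
            if mask.any():
                block_w.append(float(w[mask].sum()))
                block_bound.append(float((w[mask] * bound[mask]).sum()))
    block_w_arr = np.array(block_w)
    block_bound_arr = np.array(block_bound)
    n_blocks = len(block_w_arr)
    f_point = float(block_bound_arr.sum() / block_w_arr.sum())
    kd_point = kd_from_fraction(f_point, total_conc) if 0 < f_point < 1 else float("nan")

    kds = []
    n_skipped = 0
    for _ in range(n_boot):
        pick = rng.integers(0, n_blocks, size=n_blocks)
        f = block_bound_arr[pick].sum() / block_w_arr[pick].sum()
        if not 0.0 < f < 1.0:
            n_skipped += 1
            continue
        kds.append(kd_from_fraction(float(f), total_conc))
    if not kds:
        raise ValueError("all bootstrap resamples had degenerate bound fraction")
    lo, hi = np.percentile(kds, [2.5, 97.5])
    return {
        "kd": kd_point,
        "bound_fraction": f_point,
        "interval": (float(lo), float(hi)),
        "n_blocks": n_blocks,
        "n_boot": n_boot,
        "n_skipped": n_skipped,
    }
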
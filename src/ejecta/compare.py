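"""Comparison of simulated complex counts with an experimental signal.

Both series live on the kinetic-energy-per-projectile-molecule axis
(E_total/n, with E_total = 20 keV for every projectile size), are scaled to
their respective maxima, and compared point by point after an inner join on
the projectile size n (joining on n avoids float-equality pitfalls on the
energy axis). The experimental intensities are user-supplied (they are
digitized from a published figure and not tabulated anywhere), so nothing is
hard-coded here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_E_TOTAL = 20000.0   # eV: every projectile carries 20 keV
DEFAULT_DIVERGENCE_THRESHOLD = 0.2


def energy_per_molecule(n, e_total: float = DEFAULT_E_TOTAL):
    """Kinetic energy per projectile molecule (eV) for size-n clusters."""
    n_arr = np.asarray(n)
    if np.any(n_arr < 1):
        raise ValueError("projectile size must be at least 1 molecule")
    out = e_total / n_arr
    return float(out) if np.isscalar(n) else out


def make_series(sizes, values, e_total: float = DEFAULT_E_TOTAL) -> pd.DataFrame:
    """Assemble a signal series as a DataFrame (n, energy_per_molecule, value)."""
    sizes = np.asarray(sizes, dtype=np.int64)
    values = np.asarray(values, dtype=float)
    if len(sizes) != len(values):
        raise ValueError("sizes and values differ in length")
    if np.any(values < 0):
        raise ValueError("signal values must be non-negative")
    df = pd.DataFrame({"n": sizes,
                       "energy_per_molecule": energy_per_molecule(sizes, e_total),
                       "value": values})
    return df.sort_values("n", ignore_index=True)


def read_signal_csv(path, e_total: float = DEFAULT_E_TOTAL) -> pd.DataFrame:
    """Read an experimental CSV with columns (n, intensity)."""
    raw = pd.read_csv(path, comment="#")
    cols = list(raw.columns[:2])
    return make_series(raw[cols[0]].to_numpy(), raw[cols[1]].to_numpy(), e_total)


def scale_to_max(series: pd.DataFrame) -> pd.DataFrame:
    """Divide the value column by its maximum (maximum maps to 1.0)."""
    vmax = float(series["value"].max())
    if not vmax > 0:
        raise ValueError("cannot normalize an all-zero series")
    out = series.copy()
    out["value"] = out["value"] / vmax
    return out


@dataclass
class ComparisonReport:
    """Point-by-point agreement of two max-normalized series."""

    table: pd.DataFrame          # n, energy_per_molecule, simulated, experimental, deviation
    max_abs_deviation: float
    divergence_threshold: float
    divergent_energies: np.ndarray   # energies/molecule where |dev| > threshold

    @property
    def divergence_region(self) -> tuple[float, float] | None:
        """(min, max) energy per molecule of the flagged region, or None."""
        if len(self.divergent_energies) == 0:
            return None
        return (float(self.divergent_energies.min()),
                float(self.divergent_energies.max()))


def compare_series(simulated: pd.DataFrame, experimental: pd.DataFrame,
                   divergence_threshold: float = DEFAULT_DIVERGENCE_THRESHOLD
                   ) -> ComparisonReport:
    """Compare two series after max-normalization (inner join on n).

    The deviation is experimental − simulated per joined point; points where
    |deviation| exceeds ``divergence_threshold`` form the flagged divergence
    region. Normalization is applied here, so the report is invariant under
    rescaling either input by a positive constant.
    """
    sim = scale_to_max(simulated)
    exp = scale_to_max(experimental)
    merged = pd.merge(sim, exp, on="n", suffixes=("_sim", "_exp"))
    if merged.empty:
        raise ValueError("series share no projectile sizes")
    table = pd.DataFrame({
        "n": merged["n"],
        "energy_per_molecule": merged["energy_per_molecule_sim"],
        "simulated": merged["value_sim"],
        "experimental": merged["value_exp"],
    })
    table["deviation"] = table["experimental"] - table["simulated"]
    table["ratio"] = np.where(table["simulated"] > 0,
                              table["experimental"] / table["simulated"], np.inf)
    flagged = table.loc[table["deviation"].abs() > divergence_threshold,
                        "energy_per_molecule"].to_numpy()
    return ComparisonReport(table, float(table["deviation"].abs().max()),
                            divergence_threshold, flagged)
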
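"""Replicate-band objective: compare simulated and measured trajectories.

Measurements live on three layers — total protein and mRNA in absolute
concentration (copies per µl), phosphoprotein as relative intensities — in
biological replicates at shared time points.  The fit objective is a
band-gated, scale-normalized sum of squares:

* a simulated point that falls strictly inside the min–max band of the
  replicates contributes nothing (gate α = 0; α = 1 strictly outside,
  α = 1/2 exactly on a boundary, the literal sgn(0) = 0 convention);
* outside the band, the residual against the replicate mean is squared and,
  on absolute layers, divided by the squared time-averaged mean
  concentration of that biomolecule so that abundant and scarce species
  weigh equally;
* the phospho layer has no absolute scale: both simulation and each
  replicate series are mean-normalized over the time course (divided by
  their own time-mean) before the same band-gated squared residual.

Layer sums Sp, Sph, SRNA add up to Stotal, and the summary statistic
Ψ = sqrt(Stotal) / (#measured values) condenses the fit into a single
per-measurement figure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .compiler import AggregationMatrix, Form, ReactionSystem
from .ode import Trajectory

logger = logging.getLogger(__name__)

LAYERS = ("protein", "phospho", "rna")

#: which layers carry absolute concentrations vs relative intensities
DEFAULT_LAYER_MODE = {
    "protein": "absolute",
    "phospho": "mean_normalized",
    "rna": "absolute",
}


class DatasetError(ValueError):
    pass


@dataclass
class ExperimentalDataset:
    """Tidy multi-layer time-course measurements with replicates.

    ``table`` columns: gene, layer, condition, time_h, replicate, value.
    RNA measurements may be stored as per-cell counts (``rna_units =
    "counts"``), in which case they are converted to copies per µl by the
    estimated cell volume on access, keeping data and simulation on one
    scale.
    """

    table: pd.DataFrame
    layer_mode: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_LAYER_MODE))
    rna_units: str = "per_ul"
    cell_volume_ul: float = 8.0

    REQUIRED = ("gene", "layer", "condition", "time_h", "replicate", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise DatasetError(f"expression table is missing columns {missing}")
        if self.rna_units not in ("per_ul", "counts"):
            raise DatasetError(f"unknown rna_units {self.rna_units!r}")
        # replicate matrices are cached; the table is treated as immutable
        self._cache: dict[tuple, np.ndarray] = {}

    # -- I/O ------------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path, **kw) -> "ExperimentalDataset":
        return cls(pd.read_csv(path), **kw)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    # -- access ----------------------------------------------------------
    @property
    def conditions(self) -> list[str]:
        return sorted(self.table["condition"].unique())

    def times(self, condition: str) -> np.ndarray:
        sub = self.table[self.table["condition"] == condition]
        return np.sort(sub["time_h"].unique())

    def genes(self, layer: str, condition: str | None = None) -> list[str]:
        key = ("genes", layer, condition)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        sub = self.table[self.table["layer"] == layer]
        if condition is not None:
            sub = sub[sub["condition"] == condition]
        out = sorted(sub["gene"].unique())
        self._cache[key] = out
        return out

    def _convert(self, layer: str, values: np.ndarray) -> np.ndarray:
        if layer == "rna" and self.rna_units == "counts":
            return values / self.cell_volume_ul
        return values

    def replicate_matrix(self, gene: str, layer: str, condition: str,
                         times: np.ndarray | None = None) -> np.ndarray:
        """(n_times, n_replicates) array of converted values; NaN = missing."""
        key = (gene, layer, condition,
               tuple(times) if times is not None else None)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        sub = self.table[
            (self.table["gene"] == gene) & (self.table["layer"] == layer)
            & (self.table["condition"] == condition)
        ]
        if times is None:
            times = self.times(condition)
        reps = sorted(sub["replicate"].unique())
        out = np.full((len(times), max(len(reps), 1)), np.nan)
        t_index = {t: i for i, t in enumerate(times)}
        r_index = {r: i for i, r in enumerate(reps)}
        for _, row in sub.iterrows():
            ti = t_index.get(row["time_h"])
            if ti is not None:
                out[ti, r_index[row["replicate"]]] = row["value"]
        out = self._convert(layer, out)
        self._cache[key] = out
        return out

    def value_at(self, gene: str, layer: str, condition: str, time_h: float) -> float:
        """Replicate-mean measurement at one time point (converted units)."""
        sub = self.table[
            (self.table["gene"] == gene) & (self.table["layer"] == layer)
            & (self.table["condition"] == condition)
            & (self.table["time_h"] == time_h)
        ]
        if sub.empty:
            raise DatasetError(
                f"no {layer} measurement for {gene} at t={time_h} in {condition}")
        return float(self._convert(layer, sub["value"].to_numpy()).mean())


@dataclass
class ObjectiveReport:
    Sp: float
    Sph: float
    SRNA: float
    Stotal: float
    psi: float
    n_values: int
    n_cells: int
    in_band_fraction: float
    residuals: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "Sp": self.Sp, "Sph": self.Sph, "SRNA": self.SRNA,
            "Stotal": self.Stotal, "psi": self.psi,
            "n_values": self.n_values, "n_cells": self.n_cells,
            "in_band_fraction": self.in_band_fraction,
        }


# ---------------------------------------------------------------------------
# initial state

def initial_state(
    dataset: ExperimentalDataset,
    sys_: ReactionSystem,
    condition: str,
    phospho_fraction: float = 0.30,
    cell_volume_ul: float = 8.0,
) -> np.ndarray:
    """Construct X(0) from time-0 measurements and basal heuristics.

    The measured total protein concentration T of each gene is split
    ``phospho_fraction``·T to the phosphorylated form and the remainder to
    the unmodified form (phospho-enriched measurements carry no absolute
    scale, so the split is a population-level approximation).  The split
    only applies when the model actually carries a phospho form of the
    gene; otherwise the unmodified form receives the full total.  mRNA elements
    take the measured time-0 concentration (counts divided by the cell
    volume when stored as counts).  Each regulated gene's free promoter
    starts at two copies per cell volume with no TF bound; complexes,
    ubiquitinated forms and every unmeasured element start at 0.
    """
    t0 = 0.0
    times = dataset.times(condition)
    if len(times):
        t0 = float(times[0])
    X0 = np.zeros(sys_.n_elements)
    measured_p = set(dataset.genes("protein", condition))
    measured_rna = set(dataset.genes("rna", condition))
    has_phospho = {el.gene for el in sys_.elements if el.form is Form.PHOSPHO}
    for el in sys_.elements:
        if el.form is Form.PROTEIN and el.gene in measured_p:
            try:
                total = dataset.value_at(el.gene, "protein", condition, t0)
            except DatasetError as err:
                raise DatasetError(
                    f"missing time-0 protein measurement for {el.gene}") from err
            frac = phospho_fraction if el.gene in has_phospho else 0.0
            X0[el.index] = (1.0 - frac) * total
        elif el.form is Form.PHOSPHO and el.gene in measured_p:
            total = dataset.value_at(el.gene, "protein", condition, t0)
            X0[el.index] = phospho_fraction * total
        elif el.form is Form.RNA and el.gene in measured_rna:
            X0[el.index] = dataset.value_at(el.gene, "rna", condition, t0)
        elif el.form is Form.DNA_FREE:
            X0[el.index] = 2.0 / cell_volume_ul
    return X0


# ---------------------------------------------------------------------------
# scoring primitives

def aggregate_outputs(traj: Trajectory, agg: AggregationMatrix) -> dict[str, np.ndarray]:
    """Per-layer simulated biomolecule series Y_layer = C_layer · X(t).

    Returns arrays of shape (n_biomolecules_in_layer, n_times).
    """
    out = {}
    for layer in LAYERS:
        C, _genes = agg.layer(layer)
        out[layer] = np.asarray(C @ traj.states.T)
    return out


def mean_normalize(series: np.ndarray) -> np.ndarray:
    """Divide a time series by its own mean (result averages to 1)."""
    series = np.asarray(series, dtype=float)
    mean = np.nanmean(series)
    if not np.isfinite(mean) or mean == 0:
        raise ValueError("cannot mean-normalize a series with zero mean")
    return series / mean


def alpha(y: float, replicates: np.ndarray) -> float:
    """Band gate: 0 inside the replicate min–max band, 1 outside, 1/2 on it."""
    reps = np.asarray(replicates, dtype=float)
    reps = reps[np.isfinite(reps)]
    if reps.size == 0:
        raise ValueError("alpha needs at least one replicate")
    return 0.5 * np.sign((y - reps.max()) * (y - reps.min())) + 0.5


def layer_S(
    Y: np.ndarray,
    genes: list[str],
    dataset: ExperimentalDataset,
    layer: str,
    condition: str,
    times: np.ndarray,
    mode: str,
    collect_rows: bool = True,
) -> tuple[float, int, int, int, list[dict]]:
    """Band-gated sum of squares for one layer.

    Returns (S, n_values_used, n_cells_used, n_cells_in_band, residual rows).
    ``mode`` is "absolute" (residuals scaled by the squared time-averaged
    mean concentration) or "mean_normalized" (simulation and each replicate
    series divided by their own time-means first; no further scaling).
    """
    S = 0.0
    n_values = 0
    n_cells = 0
    n_in_band = 0
    rows: list[dict] = []
    for i, gene in enumerate(genes):
        e = dataset.replicate_matrix(gene, layer, condition, times)  # (T, R)
        y = np.asarray(Y[i], dtype=float)
        if mode == "mean_normalized":
            col_means = np.nanmean(e, axis=0)  # per-replicate time-mean
            if np.any(~np.isfinite(col_means)) or np.any(col_means == 0):
                logger.warning("skipping %s/%s: zero-mean replicate series", layer, gene)
                continue
            e = e / col_means
            y = mean_normalize(y)
            scale = 1.0
        elif mode == "absolute":
            e_tilde = np.nanmean(np.nanmean(e, axis=1))
            if not np.isfinite(e_tilde) or e_tilde == 0:
                logger.warning("skipping %s/%s: zero mean concentration", layer, gene)
                continue
            scale = e_tilde
        else:
            raise ValueError(f"unknown layer mode {mode!r}")
        for j in range(len(times)):
            reps = e[j][np.isfinite(e[j])]
            if reps.size == 0:
                continue
            a = alpha(y[j], reps)
            d = y[j] - reps.mean()
            term = a * (d / scale) ** 2
            S += term
            n_values += reps.size
            n_cells += 1
            if a == 0.0:
                n_in_band += 1
            if collect_rows:
                rows.append({"gene": gene, "layer": layer, "time_h": times[j],
                             "y": y[j], "e_mean": reps.mean(), "alpha": a,
                             "term": term})
    return S, n_values, n_cells, n_in_band, rows


def score_condition(
    traj: Trajectory,
    agg: AggregationMatrix,
    dataset: ExperimentalDataset,
    condition: str,
    with_residuals: bool = False,
) -> ObjectiveReport:
    """Full objective for one condition: Sp, Sph, SRNA, Stotal and Ψ."""
    Ys = aggregate_outputs(traj, agg)
    per_layer = {}
    n_values = n_cells = n_in_band = 0
    all_rows: list[dict] = []
    for layer in LAYERS:
        _C, genes = agg.layer(layer)
        mode = dataset.layer_mode.get(layer, DEFAULT_LAYER_MODE[layer])
        genes_with_data = set(dataset.genes(layer, condition))
        keep = [i for i, g in enumerate(genes) if g in genes_with_data]
        if not keep:
            per_layer[layer] = 0.0
            continue
        S, nv, nc, nb, rows = layer_S(
            Ys[layer][keep], [genes[i] for i in keep], dataset, layer,
            condition, traj.times, mode, collect_rows=with_residuals)
        per_layer[layer] = S
        n_values += nv
        n_cells += nc
        n_in_band += nb
        all_rows.extend(rows)
    Sp, Sph, SRNA = per_layer["protein"], per_layer["phospho"], per_layer["rna"]
    Stotal = Sp + Sph + SRNA
    return ObjectiveReport(
        Sp=Sp, Sph=Sph, SRNA=SRNA, Stotal=Stotal,
        psi=psi_from_counts(Stotal, n_values),
        n_values=n_values, n_cells=n_cells,
        in_band_fraction=(n_in_band / n_cells) if n_cells else 0.0,
        residuals=pd.DataFrame(all_rows) if with_residuals else None,
    )


def total_objective(Sp: float, Sph: float, SRNA: float,
                    m_biomolecules: int, n_times: int, r_reps: int) -> ObjectiveReport:
    """Combine layer sums into Stotal and Ψ with explicit counts."""
    Stotal = Sp + Sph + SRNA
    n_values = m_biomolecules * n_times * r_reps
    return ObjectiveReport(Sp=Sp, Sph=Sph, SRNA=SRNA, Stotal=Stotal,
                           psi=psi(Stotal, m_biomolecules, n_times, r_reps),
                           n_values=n_values, n_cells=m_biomolecules * n_times,
                           in_band_fraction=float("nan"))


def psi(Stotal: float, m_biomolecules: int, n_times: int, r_reps: int) -> float:
    """Summary statistic Ψ = sqrt(Stotal) / (m · n · r).

    The per-measurement root of the band-gated sum of squares: the square
    root of the total objective divided by the number of individual
    measured values (biomolecules × time points × replicates).
    """
    if min(m_biomolecules, n_times, r_reps) <= 0:
        raise ValueError("counts must be positive")
    return psi_from_counts(Stotal, m_biomolecules * n_times * r_reps)


def psi_from_counts(Stotal: float, n_values: int) -> float:
    if Stotal < 0:
        raise ValueError("Stotal must be nonnegative")
    if n_values == 0:
        return 0.0
    return float(np.sqrt(Stotal) / n_values)
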
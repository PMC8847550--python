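"""Dual-zone material-model optimization against physical rigidities.

The procedure mirrors the validation workflow for callus constitutive
models: the operated cohort is split (stratified by experimental dataset)
into Training and Testing groups; for each candidate soft-callus modulus
E_sc in {0.5, 5, 50, 500} MPa the density cutoff rho_cut is swept coarsely
from 0 to 1500 mgHA/cm**3 in 100 mgHA/cm**3 steps (16 levels), the RMSE
between virtual (VTR) and measured (GJ) rigidity over the Training group is
minimized, and the bracket around the coarse minimum is refined at a
5 mgHA/cm**3 pitch. Each refined optimum is then evaluated on the held-out
Testing group with the full agreement battery.

Finite-element evaluations are cached per (specimen, E_sc, soft-element
set): for a given specimen the set of elements below a cutoff is fully
determined by how many of its sorted densities fall below it, so refinement
steps that do not move any element across the threshold are free.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pipeline, stats
from .materials import E_SC_CANDIDATES_MPA, DualZoneModel, MaterialLaw, OVINE_LAW

__all__ = [
    "CohortSplit",
    "ResponseSurface",
    "OptimizationResult",
    "VtrEvaluator",
    "split_cohort",
    "coarse_sweep",
    "refine_minimum",
    "evaluate_on_group",
    "coarse_cutoff_grid",
    "COARSE_STEP",
    "REFINE_STEP",
    "RHO_CUT_SPAN",
]

COARSE_STEP = 100.0  # mgHA/cm3
REFINE_STEP = 5.0  # mgHA/cm3
RHO_CUT_SPAN = (0.0, 1500.0)  # mgHA/cm3

_log = logging.getLogger(__name__)


def coarse_cutoff_grid(span=RHO_CUT_SPAN, step=COARSE_STEP) -> np.ndarray:
    """Inclusive cutoff grid; the default span/step gives 16 levels."""
    lo, hi = span
    return np.arange(lo, hi + 0.5 * step, step, dtype=np.float64)


@dataclass(frozen=True)
class CohortSplit:
    """Disjoint Training/Testing id lists, stratified by dataset label."""

    training_ids: tuple[str, ...]
    testing_ids: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if set(self.training_ids) & set(self.testing_ids):
            raise ValueError("training and testing groups overlap")


def split_cohort(specimens, seed: int = 0) -> CohortSplit:
    """Stratified random Training/Testing split of the operated cohort.

    Within every experimental dataset the group sizes differ by at most
    one; which group receives the extra specimen of an odd-sized dataset
    alternates across datasets so overall group sizes stay as balanced as
    possible (a (7, 18, 8) cohort splits 17/16).
    """
    by_label: dict[int, list[str]] = {}
    for sp in specimens:
        by_label.setdefault(sp.dataset_label, []).append(sp.id)
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    extra_to_train = True
    for label in sorted(by_label):
        ids = sorted(by_label[label])
        if len(ids) < 2:
            raise ValueError(
                f"dataset {label} has fewer than 2 specimens; stratified split unsatisfiable"
            )
        ids = [ids[i] for i in rng.permutation(len(ids))]
        n_train = len(ids) // 2
        if len(ids) % 2:
            if extra_to_train:
                n_train += 1
            extra_to_train = not extra_to_train
        train.extend(ids[:n_train])
        test.extend(ids[n_train:])
    return CohortSplit(tuple(train), tuple(test), seed)


class VtrEvaluator:
    """Caches meshes and FE solves across the optimization grid.

    Cache key: ``(specimen id, E_sc, number of sub-cutoff elements)`` — for
    one specimen the soft-element set is a prefix of its sorted density
    vector, so two cutoffs straddling no element density share a solve.
    """

    def __init__(
        self,
        specimens,
        law: MaterialLaw = OVINE_LAW,
        threshold: float = pipeline.DEFAULT_SEGMENTATION_THRESHOLD,
        poisson: float = 0.3,
        solver_tol: float = 1e-8,
    ):
        self.specimens = {sp.id: sp for sp in specimens}
        self.law = law
        self.threshold = threshold
        self.poisson = poisson
        self.solver_tol = solver_tol
        self._cache: dict[tuple[str, float, int], float] = {}
        self._sorted_rho: dict[str, np.ndarray] = {}
        self.n_fe_solves = 0

    def _soft_count(self, specimen_id: str, rho_cut: float) -> int:
        if specimen_id not in self._sorted_rho:
            mesh = self.specimens[specimen_id].mesh(self.threshold)
            self._sorted_rho[specimen_id] = np.sort(mesh.element_density)
        return int(np.searchsorted(self._sorted_rho[specimen_id], rho_cut, side="left"))

    def vtr(self, specimen_id: str, e_sc: float, rho_cut: float) -> float:
        key = (specimen_id, float(e_sc), self._soft_count(specimen_id, rho_cut))
        if key not in self._cache:
            model = DualZoneModel(law=self.law, e_sc=e_sc, rho_cut=rho_cut, poisson=self.poisson)
            mesh = self.specimens[specimen_id].mesh(self.threshold)
            t0 = time.perf_counter()
            result = pipeline.virtual_torsion_test(mesh, model, self.solver_tol)
            self._cache[key] = result.vtr
            self.n_fe_solves += 1
            _log.debug(
                "FE solve %s E_sc=%g rho_cut=%g: VTR=%.6g (%.2f s)",
                specimen_id, e_sc, rho_cut, result.vtr, time.perf_counter() - t0,
            )
        return self._cache[key]

    def vtr_table(self, ids, e_sc: float, rho_cut: float) -> np.ndarray:
        return np.array([self.vtr(i, e_sc, rho_cut) for i in ids])


@dataclass
class ResponseSurface:
    """RMSE(E_sc, rho_cut) over a specimen group, with per-specimen VTRs."""

    e_sc_levels: tuple[float, ...]
    rho_cut_levels: np.ndarray
    rmse: np.ndarray  # (n_esc, n_cut)
    per_specimen_vtr: pd.DataFrame  # index id, columns (e_sc, rho_cut)
    specimen_ids: tuple[str, ...]
    evaluator: VtrEvaluator = field(repr=False, default=None)
    failures: list = field(default_factory=list)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.rmse, index=list(self.e_sc_levels), columns=list(self.rho_cut_levels)
        )
        df.index.name = "e_sc_MPa"
        df.columns.name = "rho_cut_mgHA_cm3"
        df.to_csv(path)


@dataclass
class OptimizationResult:
    """Refined optimum (rho_cut, min RMSE) per candidate E_sc level."""

    optima: list[dict]  # {"e_sc", "rho_cut_opt", "rmse_min"}
    coarse_step: float = COARSE_STEP
    refinement_step: float = REFINE_STEP

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.optima)


def _group_rmse(evaluator, ids, gj, e_sc, rho_cut) -> float:
    return stats.rmse(evaluator.vtr_table(ids, e_sc, rho_cut), gj)


def coarse_sweep(
    training,
    e_sc_levels=E_SC_CANDIDATES_MPA,
    rho_span=RHO_CUT_SPAN,
    step: float = COARSE_STEP,
    evaluator: VtrEvaluator | None = None,
    **evaluator_kwargs,
) -> ResponseSurface:
    """Evaluate the Training-group RMSE on the full coarse (E_sc, rho_cut) grid.

    Every training specimen must carry a ``measured_gj``. FE failures at a
    grid point are recorded on the surface (with the offending specimen and
    parameters) and surface entries involving them are left NaN rather than
    silently dropped.
    """
    ids = tuple(sp.id for sp in training)
    gj = np.array([sp.measured_gj for sp in training], dtype=np.float64)
    if np.any(~np.isfinite(gj)):
        raise ValueError("every training specimen needs a measured_gj")
    if evaluator is None:
        evaluator = VtrEvaluator(training, **evaluator_kwargs)
    cutoffs = coarse_cutoff_grid(rho_span, step)
    e_sc_levels = tuple(float(e) for e in e_sc_levels)
    rmse_mat = np.full((len(e_sc_levels), len(cutoffs)), np.nan)
    failures: list[dict] = []
    vtr_cols: dict[tuple[float, float], np.ndarray] = {}
    for i, e_sc in enumerate(e_sc_levels):
        for j, cut in enumerate(cutoffs):
            try:
                vtr = evaluator.vtr_table(ids, e_sc, cut)
            except Exception as exc:  # recorded, not silently skipped
                failures.append({"e_sc": e_sc, "rho_cut": float(cut), "error": repr(exc)})
                continue
            vtr_cols[(e_sc, float(cut))] = vtr
            rmse_mat[i, j] = stats.rmse(vtr, gj)
    per_specimen = pd.DataFrame(vtr_cols, index=list(ids))
    return ResponseSurface(
        e_sc_levels=e_sc_levels,
        rho_cut_levels=cutoffs,
        rmse=rmse_mat,
        per_specimen_vtr=per_specimen,
        specimen_ids=ids,
        evaluator=evaluator,
        failures=failures,
    )


def refine_minimum(surface: ResponseSurface, training, step: float = REFINE_STEP) -> OptimizationResult:
    """Refine each E_sc's coarse minimum at a fine cutoff pitch.

    The refinement grid covers the whole bracket between the two coarse
    neighbours of the coarse minimum (interior side only when the minimum
    sits on a grid boundary); ties are broken toward the lower cutoff,
    i.e. toward the single-zone limit.
    """
    evaluator = surface.evaluator
    if evaluator is None:
        raise ValueError("surface carries no evaluator; rerun coarse_sweep")
    ids = surface.specimen_ids
    by_id = {sp.id: sp.measured_gj for sp in training}
    gj = np.array([by_id[i] for i in ids], dtype=np.float64)
    optima = []
    for i, e_sc in enumerate(surface.e_sc_levels):
        row = surface.rmse[i]
        if np.all(np.isnan(row)):
            raise ValueError(f"no evaluable coarse grid points for E_sc={e_sc}")
        j_min = int(np.nanargmin(row))
        lo = surface.rho_cut_levels[max(j_min - 1, 0)]
        hi = surface.rho_cut_levels[min(j_min + 1, len(row) - 1)]
        fine = np.arange(lo, hi + 0.5 * step, step)
        best_cut, best_rmse = None, np.inf
        for cut in fine:
            # coarse endpoints hit the evaluator cache, so re-querying is free
            r = _group_rmse(evaluator, ids, gj, e_sc, float(cut))
            if r < best_rmse - 1e-15:  # strict improvement; ties keep lower cutoff
                best_cut, best_rmse = float(cut), float(r)
        optima.append({"e_sc": e_sc, "rho_cut_opt": best_cut, "rmse_min": best_rmse})
    return OptimizationResult(optima=optima, coarse_step=float(np.diff(surface.rho_cut_levels).mean()), refinement_step=step)


def evaluate_on_group(group, optima: OptimizationResult, evaluator: VtrEvaluator | None = None, **evaluator_kwargs) -> pd.DataFrame:
    """Apply each optimized (E_sc, rho_cut) pair to a held-out group.

    Returns one row per optimum with RMSE, Pearson r/R**2/p, the agreement
    verdict (RMSE < SD of the group's measured rigidities) and the VTR
    summary statistics.
    """
    if len(group) < 3:
        raise ValueError("group evaluation requires >= 3 specimens")
    ids = [sp.id for sp in group]
    gj = np.array([sp.measured_gj for sp in group], dtype=np.float64)
    if np.any(~np.isfinite(gj)):
        raise ValueError("every group specimen needs a measured_gj")
    if evaluator is None:
        evaluator = VtrEvaluator(group, **evaluator_kwargs)
    rows = []
    for opt in optima.optima:
        vtr = evaluator.vtr_table(ids, opt["e_sc"], opt["rho_cut_opt"])
        report = stats.agreement_report(vtr, gj)
        mean_vtr, sd_vtr = stats.describe(vtr)
        rows.append(
            {
                "e_sc": opt["e_sc"],
                "rho_cut_opt": opt["rho_cut_opt"],
                "rmse": report.rmse,
                "r": report.r,
                "r_squared": report.r_squared,
                "p": report.p_value,
                "strength": report.strength,
                "datum_sd": report.datum_sd,
                "agreement_pass": report.passes,
                "vtr_mean": mean_vtr,
                "vtr_sd": sd_vtr,
            }
        )
    return pd.DataFrame(rows)
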
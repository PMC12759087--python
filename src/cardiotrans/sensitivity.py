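"""Sobol' global sensitivity analysis of biomarkers.

Input samples follow Saltelli's radial scheme: a base Sobol' sequence of
dimension 2D provides matrices A and B (n rows each); the cross matrices
AB_i (column i of A replaced from B) and BA_i give n*(2D+2) model runs and
allow first-, second- and total-order index estimation.  Total-effect
indices use the Jansen estimator

    ST_i = E[(f(A) - f(AB_i))^2] / (2 * Var f),

first-order indices the Saltelli-2010 estimator.  Indices are clipped at
zero (estimator noise) and normalised per output by the maximum across
inputs, so that for each biomarker the most influential input scores 1;
inputs below 0.1 for every output are reported insensitive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import qmc

__all__ = [
    "SensitivityProblem",
    "SensitivityResult",
    "saltelli_sample",
    "evaluate_batch",
    "impute_missing",
    "total_effect_indices",
    "INSENSITIVITY_THRESHOLD",
]

INSENSITIVITY_THRESHOLD = 0.1


@dataclass(frozen=True)
class SensitivityProblem:
    """Names, bounds and base sample size of one analysis."""

    names: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]
    n: int = 1024
    outputs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.names) != len(self.bounds):
            raise ValueError("one (lb, ub) pair per input required")
        if len(self.names) == 0:
            raise ValueError("at least one input required")
        for lb, ub in self.bounds:
            if not (np.isfinite(lb) and np.isfinite(ub) and lb < ub):
                raise ValueError("bounds must be finite with lb < ub")
        if self.n < 2:
            raise ValueError("base sample size n must be >= 2")

    @property
    def dim(self) -> int:
        return len(self.names)

    @property
    def n_samples(self) -> int:
        """Total rows of the Saltelli scheme, n*(2D+2)."""
        return self.n * (2 * self.dim + 2)


@dataclass(frozen=True)
class SensitivityResult:
    """Total-effect matrix and its per-output normalisation."""

    problem: SensitivityProblem
    st: np.ndarray   # (inputs, outputs), clipped at 0
    stn: np.ndarray  # st / per-output max
    excluded_fraction: float = 0.0

    @property
    def insensitive_inputs(self) -> tuple[str, ...]:
        mask = np.all(self.stn < INSENSITIVITY_THRESHOLD, axis=1)
        return tuple(np.asarray(self.problem.names)[mask])


def saltelli_sample(problem: SensitivityProblem) -> np.ndarray:
    """Saltelli sample matrix with n*(2D+2) rows inside the bounds box.

    Row layout: n rows of A, n of B, then for each input i the n rows of
    AB_i followed by the n rows of BA_i.  Deterministic (unscrambled
    Sobol' base sequence).
    """
    d = problem.dim
    n = problem.n
    if n & (n - 1) != 0:
        warnings.warn(
            "base sample size is not a power of two; Sobol' sequence balance "
            "properties degrade",
            UserWarning,
            stacklevel=2,
        )
    sob = qmc.Sobol(2 * d, scramble=False)
    base = sob.random(n)
    a, b = base[:, :d], base[:, d:]
    blocks = [a, b]
    for i in range(d):
        ab = a.copy()
        ab[:, i] = b[:, i]
        blocks.append(ab)
        ba = b.copy()
        ba[:, i] = a[:, i]
        blocks.append(ba)
    unit = np.vstack([blocks[0], blocks[1]] + blocks[2:])
    lo = np.array([lb for lb, _ in problem.bounds])
    hi = np.array([ub for _, ub in problem.bounds])
    return lo + unit * (hi - lo)


def evaluate_batch(
    samples: np.ndarray,
    runner: Callable[[np.ndarray], Sequence[float] | None],
    n_outputs: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the model on every sample row; mask failures and missing values.

    ``runner`` maps one input row to a biomarker vector; it may return None
    (or raise) for abnormal/unstable samples, and individual entries may be
    NaN.  Returns (outputs, mask) where mask is True for missing entries.
    """
    n = samples.shape[0]
    out = np.full((n, n_outputs), np.nan)
    for i in range(n):
        try:
            row = runner(samples[i])
        except Exception:
            row = None
        if row is not None:
            row = np.asarray(row, dtype=float)
            if row.shape != (n_outputs,):
                raise ValueError("runner returned a vector of wrong length")
            out[i] = row
    mask = ~np.isfinite(out)
    return out, mask


def impute_missing(outputs: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace masked entries by the column mean of the unmasked ones."""
    out = outputs.copy()
    for j in range(out.shape[1]):
        col_mask = mask[:, j]
        if col_mask.all():
            raise ValueError(f"output column {j} has no valid values to impute from")
        if col_mask.any():
            out[col_mask, j] = out[~col_mask, j].mean()
    return out


def _split_blocks(problem: SensitivityProblem, outputs: np.ndarray):
    d, n = problem.dim, problem.n
    if outputs.shape[0] != problem.n_samples:
        raise ValueError(
            f"output rows ({outputs.shape[0]}) do not match the Saltelli "
            f"layout ({problem.n_samples})"
        )
    fa = outputs[:n]
    fb = outputs[n : 2 * n]
    fab = np.empty((d, n, outputs.shape[1]))
    for i in range(d):
        fab[i] = outputs[(2 + 2 * i) * n : (3 + 2 * i) * n]
    return fa, fb, fab


def total_effect_indices(
    problem: SensitivityProblem,
    outputs: np.ndarray,
    excluded_fraction: float = 0.0,
) -> SensitivityResult:
    """Total-effect Sobol' indices (Jansen estimator), clipped and normalised."""
    fa, fb, fab = _split_blocks(problem, outputs)
    allf = np.vstack([fa, fb])
    var = allf.var(axis=0, ddof=0)
    var = np.where(var > 0, var, np.inf)  # constant output -> ST 0
    d = problem.dim
    st = np.empty((d, outputs.shape[1]))
    for i in range(d):
        st[i] = 0.5 * np.mean((fa - fab[i]) ** 2, axis=0) / var
    st = np.clip(st, 0.0, None)
    col_max = st.max(axis=0)
    col_max = np.where(col_max > 0, col_max, 1.0)
    stn = st / col_max
    return SensitivityResult(problem, st, stn, excluded_fraction)


def drug_response_problem(targets: Sequence[str], n: int = 1024) -> SensitivityProblem:
    """Drug-response preset: scaling factors in [0.6, 1.0] per target.

    With the 8-protein shared roster and n = 1024 this yields 18,432
    samples; outputs are the 14 characteristic biomarkers.
    """
    from .transients import ALL_BIOMARKERS

    return SensitivityProblem(
        names=tuple(targets),
        bounds=tuple((0.6, 1.0) for _ in targets),
        n=n,
        outputs=ALL_BIOMARKERS,
    )


def recalibration_screening_problem(
    params, n: int = 1024, bounds_rel: tuple[float, float] = (0.5, 1.5)
) -> SensitivityProblem:
    """Recalibration-screening preset: candidate parameters in 50-150 %.

    Inputs are the contraction-component parameters, the maximal
    conductance/rate of each drug-target protein present in the species,
    and the maximum troponin-bound Ca; outputs are the recalibration
    biomarkers.
    """
    from .models.params import TARGET_PARAM

    contraction = (
        "kTRPN", "nTRPN", "Ca50ref", "k_xb", "n_xb", "k_p", "c_a", "eta",
        "beta0", "beta1",
    )
    names = [p for p in contraction if p in params.values]
    names += [p for p in TARGET_PARAM.values() if p in params.values]
    names.append("CaTRPN_max")
    bounds = []
    for name in names:
        ref = params[name]
        bounds.append(tuple(sorted((bounds_rel[0] * ref, bounds_rel[1] * ref))))
    outputs = (
        "SLRes", "Short", "SLTP", "SLTR50", "SLTR90", "dSLMaxC", "dSLMaxR",
        "CaRes", "CaPeak", "CaTP", "CaTR50",
    )
    return SensitivityProblem(tuple(names), tuple(bounds), n, outputs)


def first_order_indices(
    problem: SensitivityProblem, outputs: np.ndarray
) -> np.ndarray:
    """First-order indices (Saltelli 2010), for internal ST >= S1 checks."""
    fa, fb, fab = _split_blocks(problem, outputs)
    allf = np.vstack([fa, fb])
    var = allf.var(axis=0, ddof=0)
    var = np.where(var > 0, var, np.inf)
    d = problem.dim
    s1 = np.empty((d, outputs.shape[1]))
    for i in range(d):
        s1[i] = np.mean(fb * (fab[i] - fa), axis=0) / var
    return s1
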
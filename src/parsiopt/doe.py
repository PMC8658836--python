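"""D-optimal design selection and hyperparameter effect analysis.

The search strategies report *which* architectures win but not *why*; a
main-effects regression on a D-optimally chosen subset of architectures
quantifies how each hyperparameter level moves NER_T.  Quantitative
factors are coded ordinally to [-1, 1] (level rank by increasing numeric
value, so the highest learning rate codes to +1); qualitative factors are
effects-coded against their first level.  The design maximising
det(X'X) is found by Fedorov exchange.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .search_space import ArchitectureConfig, Factor, HyperparameterSpace

__all__ = [
    "CodedDesign",
    "EffectModel",
    "code_matrix",
    "d_optimal_select",
    "fit_effects",
    "frequency_table",
]


def _term_names(space: HyperparameterSpace) -> list[str]:
    names = ["intercept"]
    for f in space.factors:
        if f.kind == "quantitative":
            names.append(f.name)
        else:
            # effects coding against the first (reference) level
            names.extend(f"{f.name}:{lvl}" for lvl in f.levels[1:])
    return names


def _code_factor(f: Factor, value) -> list[float]:
    if f.kind == "quantitative":
        ranks = np.argsort(np.argsort([float(v) for v in f.levels]))
        r = ranks[f.level_index(value)]
        if f.n_levels == 1:
            return [0.0]
        return [2.0 * r / (f.n_levels - 1) - 1.0]
    idx = f.level_index(value)
    cols = [0.0] * (f.n_levels - 1)
    if idx == 0:
        cols = [-1.0] * (f.n_levels - 1)
    else:
        cols[idx - 1] = 1.0
    return cols


def code_matrix(
    configs: list[ArchitectureConfig], space: HyperparameterSpace
) -> np.ndarray:
    """Runs x terms coded model matrix (intercept + main effects)."""
    rows = []
    for c in configs:
        row = [1.0]
        for f in space.factors:
            row.extend(_code_factor(f, c[f.name]))
        rows.append(row)
    return np.asarray(rows)


@dataclass
class CodedDesign:
    """A selected set of runs with its coded model matrix."""

    configs: list[ArchitectureConfig]
    space: HyperparameterSpace

    @property
    def X(self) -> np.ndarray:
        return code_matrix(self.configs, self.space)

    @property
    def term_names(self) -> list[str]:
        return _term_names(self.space)

    @property
    def n_runs(self) -> int:
        return len(self.configs)

    def log_det(self) -> float:
        sign, ld = np.linalg.slogdet(self.X.T @ self.X)
        return float(ld) if sign > 0 else -np.inf


def _log_det(xtx: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(xtx)
    return float(ld) if sign > 0 else -np.inf


def d_optimal_select(
    candidates: list[ArchitectureConfig],
    space: HyperparameterSpace,
    n_runs: int | None = None,
    seed: int | np.random.Generator = 0,
    max_sweeps: int = 100,
    rel_tol: float = 1e-9,
    max_restarts: int = 50,
) -> CodedDesign:
    """Fedorov exchange: select ``n_runs`` candidates maximising det(X'X).

    Starts from a random nonsingular subset and repeatedly swaps a design
    row for a candidate row whenever the swap increases the determinant;
    stops when a full sweep yields no relative improvement above
    ``rel_tol`` or after ``max_sweeps`` sweeps.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    C = code_matrix(candidates, space)
    p = C.shape[1]
    if n_runs is None:
        n_runs = 3 * p
    if n_runs < p:
        raise ValueError(
            f"n_runs={n_runs} below the {p} model terms: design singular"
        )
    if n_runs >= len(candidates):
        return CodedDesign(list(candidates), space)

    sel = None
    for _ in range(max_restarts):
        trial = rng.choice(len(candidates), n_runs, replace=False)
        if _log_det(C[trial].T @ C[trial]) > -np.inf:
            sel = list(trial)
            break
    if sel is None:
        raise RuntimeError(
            "could not find a nonsingular starting design after "
            f"{max_restarts} restarts"
        )

    xtx = C[sel].T @ C[sel]
    current = _log_det(xtx)
    for _sweep in range(max_sweeps):
        improved = False
        for pos in range(n_runs):
            xi = C[sel[pos]]
            base = xtx - np.outer(xi, xi)
            best_j, best_ld = None, current
            for j in range(len(candidates)):
                if j in sel:
                    continue
                xj = C[j]
                ld = _log_det(base + np.outer(xj, xj))
                if ld > best_ld + rel_tol:
                    best_ld, best_j = ld, j
            if best_j is not None:
                xtx = base + np.outer(C[best_j], C[best_j])
                sel[pos] = best_j
                current = best_ld
                improved = True
        if not improved:
            break
    return CodedDesign([candidates[i] for i in sel], space)


@dataclass
class EffectModel:
    """OLS main-effects fit: per-term coefficient, 95% CI half-width, and
    a sign flag (positive / negative / inconclusive)."""

    terms: list[str]
    coef: np.ndarray
    ci_half: np.ndarray

    @property
    def flags(self) -> list[str]:
        out = []
        for b, h in zip(self.coef, self.ci_half):
            if b - h > 0:
                out.append("positive")
            elif b + h < 0:
                out.append("negative")
            else:
                out.append("inconclusive")
        return out

    def flag(self, term: str) -> str:
        return self.flags[self.terms.index(term)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "coefficient": self.coef,
                "ci_half_width": self.ci_half,
                "flag": self.flags,
            }
        )


def fit_effects(design: CodedDesign, responses: np.ndarray) -> EffectModel:
    """Ordinary least squares of NER_T on the coded main effects, with 95%
    confidence intervals from the t distribution on (runs - terms) df."""
    X = design.X
    y = np.asarray(responses, dtype=float)
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("one response per design run required")
    if n < p + 1:
        raise ValueError(f"need at least terms+1 = {p + 1} runs, got {n}")
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < p:
        raise np.linalg.LinAlgError("rank-deficient design matrix")
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    dof = n - p
    s2 = float(resid @ resid) / dof
    se = np.sqrt(s2 * np.diag(xtx_inv))
    tcrit = stats.t.ppf(0.975, dof)
    return EffectModel(design.term_names, beta, tcrit * se)


def frequency_table(
    configs: list[ArchitectureConfig], space: HyperparameterSpace
) -> pd.DataFrame:
    """Relative level frequencies per factor over a set of configurations
    (e.g. the final GA populations or the top-k grid-search results)."""
    if not configs:
        raise ValueError("empty configuration set")
    rows = []
    n = len(configs)
    for f in space.factors:
        counts = np.zeros(f.n_levels)
        for c in configs:
            counts[f.level_index(c[f.name])] += 1
        for lvl, cnt in zip(f.levels, counts):
            rows.append(
                {"factor": f.name, "level": lvl, "frequency": cnt / n}
            )
    return pd.DataFrame(rows)
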
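"""Bayesian logistic regression of Allee probability on scenario design.

The response is Y_i = 1 when repetition i showed a strong or weak Allee
effect; the predictors are dummies for perception-neighborhood x
dispersal-distance cells, with perception neighborhoods of three or more
territories grouped (their outcome frequencies are indistinguishable), so
the default design has 9 cells.  With cell-means coding (one dummy per
cell, no intercept) and a vague Normal(0, 100^2) prior on each
coefficient, the Bernoulli-logit likelihood factorizes per cell and each
cell's posterior Allee probability p_k = logit^{-1}(beta_k) is driven by
that cell's successes and trials — these are exactly the quantities the
scenario comparison needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .diagnostics import ConvergenceReport, diagnose

__all__ = [
    "ScenarioDesign",
    "LogisticFit",
    "encode_outcomes",
    "sample_logistic",
    "summarize_probabilities",
]

DISPERSAL_ORDER = ("low", "ave", "high")
PRIOR_SD = 100.0


@dataclass(frozen=True)
class ScenarioDesign:
    """Cell labels, per-repetition cell assignment, and coding.

    ``coding="cell_means"`` (default) gives one dummy per cell and no
    intercept, so each coefficient is that cell's logit; ``"reference"``
    gives an intercept plus dummies against the first cell.  Either way
    the design is cell-saturated, so the likelihood depends on the data
    only through per-cell successes and trials.
    """

    cells: tuple  # ordered cell labels, e.g. ("1/low", ..., "3+/high")
    assignment: np.ndarray  # per-repetition cell index
    coding: str = "cell_means"

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_params(self) -> int:
        return self.n_cells

    def cell_design(self) -> np.ndarray:
        """(n_cells x n_params) matrix mapping coefficients to cell logits."""
        k = self.n_cells
        if self.coding == "cell_means":
            return np.eye(k)
        if self.coding == "reference":
            c = np.zeros((k, k))
            c[:, 0] = 1.0  # intercept
            c[1:, 1:] = np.eye(k - 1)
            return c
        raise ValueError(f"unknown coding {self.coding!r}")

    def dummy_matrix(self) -> np.ndarray:
        x = np.zeros((len(self.assignment), self.n_cells))
        x[np.arange(len(self.assignment)), self.assignment] = 1.0
        if self.coding == "cell_means":
            return x
        return x @ self.cell_design()


def _cell_label(pn: int, dispersal: str, grouping: str) -> str:
    if grouping == "pn3":
        return f"{min(int(pn), 3)}{'+' if pn >= 3 else ''}/{dispersal}"
    if grouping == "full":
        return f"{int(pn)}/{dispersal}"
    raise ValueError(f"unknown grouping {grouping!r}")


def encode_outcomes(
    outcomes,
    grouping: str = "pn3",
    drop_extinct: bool = False,
    coding: str = "cell_means",
) -> tuple[ScenarioDesign, np.ndarray]:
    """Turn classified outcomes into (design, binary responses).

    Y = 1 for strong or weak Allee; extinct repetitions count as Y = 0
    (every repetition is indexed) unless ``drop_extinct``.
    """
    if not outcomes:
        raise ValueError("no outcomes to encode")
    pn_levels = ("1", "2", "3+") if grouping == "pn3" else tuple("12345")
    cells = tuple(f"{p}/{d}" for p in pn_levels for d in DISPERSAL_ORDER)
    index = {c: i for i, c in enumerate(cells)}
    assign, ys = [], []
    for o in outcomes:
        if o.category not in ("extinct", "strong_allee", "weak_allee", "no_evidence"):
            raise ValueError(f"unknown category {o.category!r}")
        if drop_extinct and o.category == "extinct":
            continue
        pn = o.scenario["perception_territories"]
        disp = o.scenario["dispersal"]
        assign.append(index[_cell_label(pn, disp, grouping)])
        ys.append(1 if o.category in ("strong_allee", "weak_allee") else 0)
    return (
        ScenarioDesign(
            cells=cells,
            assignment=np.array(assign, dtype=int),
            coding=coding,
        ),
        np.array(ys, dtype=int),
    )


@dataclass(frozen=True)
class LogisticFit:
    design: ScenarioDesign
    draws: np.ndarray  # (chains, kept, n_cells) of beta
    successes: np.ndarray
    trials: np.ndarray
    report: ConvergenceReport

    def p_draws(self) -> np.ndarray:
        """Per-cell Allee-probability draws (any coding)."""
        m, n, p = self.draws.shape
        beta = self.draws.reshape(m * n, p)
        return expit(beta @ self.design.cell_design().T)


def _slice_sample(logf, x0: float, rng, w: float = 1.0, max_steps: int = 50) -> float:
    """One univariate slice-sampling update (stepping out + shrinkage)."""
    logy = logf(x0) + np.log(rng.random())
    u = rng.random()
    lo = x0 - u * w
    hi = lo + w
    steps = max_steps
    while steps > 0 and logf(lo) > logy:
        lo -= w
        steps -= 1
    steps = max_steps
    while steps > 0 and logf(hi) > logy:
        hi += w
        steps -= 1
    while True:
        x1 = rng.uniform(lo, hi)
        if logf(x1) > logy:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1


def sample_logistic(
    design: ScenarioDesign,
    responses: np.ndarray,
    chains: int = 3,
    iters: int = 20_000,
    burnin: int = 5_000,
    thin: int = 5,
    seed: int = 0,
) -> LogisticFit:
    """Posterior draws of the cell coefficients by slice sampling.

    The design is cell-saturated, so the log-likelihood reduces to
    sum_c s_c eta_c - n_c log(1 + e^eta_c) with eta = C beta, where C is
    the cell design matrix and (s_c, n_c) the per-cell successes and
    trials.  Under cell-means coding each coordinate's conditional is
    independent; under reference coding the coordinates are updated
    slice-within-Gibbs against the same sufficient statistics.
    """
    y = np.asarray(responses)
    k = design.n_cells
    succ = np.zeros(k)
    tri = np.zeros(k)
    np.add.at(succ, design.assignment, y)
    np.add.at(tri, design.assignment, 1)
    cmat = design.cell_design()
    p = design.n_params
    n_kept = -(-(iters - burnin) // thin)  # ceil: iteration `burnin` is kept
    draws = np.empty((chains, n_kept, p))
    seeds = np.random.SeedSequence(seed).spawn(chains)
    for c in range(chains):
        rng = np.random.default_rng(seeds[c])
        beta = rng.normal(0.0, 1.0, size=p)
        kept = 0
        for it in range(iters):
            for j in range(p):
                col = cmat[:, j]
                eta_rest = cmat @ beta - col * beta[j]

                def logf(b, col=col, eta_rest=eta_rest):
                    eta = eta_rest + col * b
                    return float(
                        succ @ eta - tri @ np.log1p(np.exp(eta))
                    ) - b * b / (2.0 * PRIOR_SD**2)

                beta[j] = _slice_sample(logf, beta[j], rng)
            if it >= burnin and (it - burnin) % thin == 0:
                draws[c, kept] = beta
                kept += 1
    if design.coding == "cell_means":
        names = [f"beta[{c}]" for c in design.cells]
    else:
        names = ["beta0"] + [f"beta[{c}]" for c in design.cells[1:]]
    report = diagnose(draws, names)
    return LogisticFit(
        design=design, draws=draws, successes=succ, trials=tri, report=report
    )


def summarize_probabilities(fit: LogisticFit) -> pd.DataFrame:
    """Posterior mean and 95% credible interval of p per cell.

    Rows are ordered by perception level then dispersal (low, ave, high),
    the layout of the scenario-probability figure.
    """
    p = fit.p_draws()
    rows = []
    for i, cell in enumerate(fit.design.cells):
        pn, disp = cell.split("/")
        rows.append(
            {
                "cell": cell,
                "perception": pn,
                "dispersal": disp,
                "trials": int(fit.trials[i]),
                "successes": int(fit.successes[i]),
                "p_mean": float(p[:, i].mean()),
                "p_2.5": float(np.quantile(p[:, i], 0.025)),
                "p_97.5": float(np.quantile(p[:, i], 0.975)),
            }
        )
    return pd.DataFrame(rows)
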
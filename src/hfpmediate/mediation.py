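"""Effect decomposition and Monte Carlo confidence intervals.

The intervention's total effect on dietary diversity is decomposed, by path
tracing in the fitted recursive system, into

* the direct effect c' (treatment -> outcome net of mediators),
* mediator-specific indirect effects a_j * b_j,
* sequential effects through market activity a_j * d_j * b_market,
* the market-alone effect a_market * b_market,

with domain sums (garden, poultry, knowledge, market activity) and the total
indirect effect.  Because the system is linear with no exposure-mediator
interactions, these products add: total = direct + total indirect, and the
total also equals the reduced-form treatment coefficient (asserted).

Uncertainty: coefficient vectors are drawn from a multivariate normal
centered at the estimates with the (cluster-robust, by default) coefficient
covariance; each effect expression is evaluated per draw and the 2.5th/97.5th
percentiles reported.  Percentile intervals are used because products of
normals are skewed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DOMAINS",
    "EffectDecomposition",
    "decompose_effects",
    "monte_carlo_ci",
    "summarize_proportions",
]

#: canonical mediator domains of the homestead-food-production intervention
DOMAINS = {
    "garden": ["crop_richness", "garden_practices"],
    "poultry": ["n_poultry", "n_eggs"],
    "knowledge": ["fg_knowledge", "dd_knowledge"],
}


@dataclass
class EffectDecomposition:
    """Point estimates (and optional Monte Carlo CIs) of the decomposition."""

    effects: dict                      # name -> point estimate
    terms: dict                        # name -> list of tuples of coefficient labels
    mediators: list
    market_feeders: list
    ci: dict = field(default_factory=dict)   # name -> (lo, hi)

    @property
    def individual_names(self):
        out = [f"indirect_{m}" for m in self.mediators]
        out += [f"via_market_{m}" for m in self.market_feeders]
        out += ["market_alone", "via_market_total"]
        return out

    @property
    def domain_names(self):
        return [n for n in self.effects
                if n.startswith(("garden", "poultry", "knowledge", "market_activity"))]

    def to_frame(self):
        import pandas as pd

        rows = []
        for name, est in self.effects.items():
            lo, hi = self.ci.get(name, (np.nan, np.nan))
            rows.append({"effect": name, "estimate": est, "ci_low": lo, "ci_high": hi})
        return pd.DataFrame(rows)


def decompose_effects(results, mediators, outcome="dds_mean", treatment="arm",
                      market="market_score", market_feeders=None,
                      domains=DOMAINS):
    """Decompose the treatment effect from a fitted path model.

    ``mediators`` excludes the market variable.  Raises ``KeyError`` naming
    any path coefficient absent from the fit, and ``RuntimeError`` if the
    decomposed total disagrees with the reduced-form treatment coefficient.
    """
    params = results.params
    if market is None:
        feeders = []
    elif market_feeders is not None:
        feeders = list(market_feeders)
    else:
        feeders = [m for m in mediators if f"{market}~{m}" in params.index]

    def coef(label):
        if label not in params.index:
            raise KeyError(f"path coefficient {label!r} not in fitted model")
        return label

    terms = {}
    for m in mediators:
        terms[f"indirect_{m}"] = [(coef(f"{m}~{treatment}"), coef(f"{outcome}~{m}"))]
    for m in feeders:
        terms[f"via_market_{m}"] = [(
            coef(f"{m}~{treatment}"), coef(f"{market}~{m}"), coef(f"{outcome}~{market}")
        )]
    if market is not None:
        terms["market_alone"] = [(coef(f"{market}~{treatment}"),
                                  coef(f"{outcome}~{market}"))]
    else:
        terms["market_alone"] = []
    terms["via_market_total"] = [t for m in feeders for t in terms[f"via_market_{m}"]]
    terms["direct"] = [(coef(f"{outcome}~{treatment}"),)]

    for dom, members in domains.items():
        members = [m for m in members if m in mediators]
        if not members:
            continue
        terms[dom] = [t for m in members for t in terms[f"indirect_{m}"]]
        terms[dom + "_with_market"] = terms[dom] + [
            t for m in members if m in feeders for t in terms[f"via_market_{m}"]
        ]
    if market is not None:
        terms["market_activity"] = terms["market_alone"] + terms["via_market_total"]
    terms["total_indirect"] = (
        [t for m in mediators for t in terms[f"indirect_{m}"]]
        + terms["via_market_total"] + terms["market_alone"]
    )
    terms["total"] = terms["direct"] + terms["total_indirect"]

    effects = {
        name: float(sum(np.prod([params[l] for l in t]) for t in tt))
        for name, tt in terms.items()
    }

    # cross-check: reduced-form treatment coefficient equals the decomposed total
    mom, cache = results.model.param.moments(results.theta)
    Pi = cache["Pi"]
    iy = results.model.endo.index(outcome)
    it = results.model.exog.index(treatment)
    reduced = float(Pi[iy, it])
    if not np.isclose(reduced, effects["total"], rtol=1e-8, atol=1e-10):
        raise RuntimeError(
            f"path-traced total {effects['total']:.6g} disagrees with "
            f"reduced-form treatment coefficient {reduced:.6g}"
        )
    return EffectDecomposition(
        effects=effects, terms=terms, mediators=list(mediators),
        market_feeders=feeders,
    )


def monte_carlo_ci(results, decomp: EffectDecomposition, n_reps: int = 10_000,
                   seed: int = 0, level: float = 0.95, vcov_kind: str = "cluster"):
    """Percentile Monte Carlo intervals for every effect in the decomposition.

    Coefficient draws use only the sub-covariance of the coefficients that
    enter effect expressions.  Returns ``decomp`` with its ``ci`` mapping
    filled; reproducible given ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    labels = sorted({l for tt in decomp.terms.values() for t in tt for l in t})
    idx = {l: i for i, l in enumerate(labels)}
    pos = [list(results.params.index).index(l) for l in labels]
    V = np.asarray(results.vcov(vcov_kind))[np.ix_(pos, pos)]
    mean = results.params.iloc[pos].to_numpy()

    w = np.linalg.eigvalsh(V)
    if w.min() < -1e-10 * max(w.max(), 1.0):
        logger.error(
            "coefficient covariance is not PSD (min eigenvalue %.3e); consider "
            "projecting to the nearest PSD matrix before drawing", w.min()
        )
        raise ValueError("non-PSD coefficient covariance for Monte Carlo draws")

    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(mean, V, size=n_reps, method="svd")
    qlo, qhi = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    for name, tt in decomp.terms.items():
        vals = np.zeros(n_reps)
        for t in tt:
            vals += np.prod(draws[:, [idx[l] for l in t]], axis=1)
        decomp.ci[name] = (float(np.percentile(vals, qlo)),
                           float(np.percentile(vals, qhi)))
    return decomp


def summarize_proportions(decomp: EffectDecomposition, tol: float = 1e-8):
    """Proportion mediated (%) for the total indirect and each domain sum.

    Flags (raises) when the total effect is too close to zero for the ratio
    to be stable."""
    total = decomp.effects["total"]
    if abs(total) < tol:
        raise ValueError(
            f"total effect {total:.3g} below tolerance; proportions unstable"
        )
    names = ["total_indirect"] + decomp.domain_names
    return {n: 100.0 * decomp.effects[n] / total for n in names}
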
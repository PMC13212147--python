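"""Specification of the recursive linear path model.

A :class:`PathModelSpec` describes a system of linear regressions among
observed variables: each endogenous variable (the seven mediators and the
outcome) is regressed on the treatment, baseline covariates and — for the
market-activity score and the outcome — on other mediators.  The directed
graph over endogenous variables must be acyclic, so the coefficient matrix B
is strictly lower triangular under a topological ordering and the system has
the reduced form eta = (I - B)^-1 (alpha + Gamma x + zeta).

Residual covariances are declared as blocks: within a block every pairwise
residual covariance is free (the default model frees the garden/poultry block
and the knowledge pair).

A small lavaan-style syntax is supported::

    dds_mean ~ arm + crop_richness + market_score
    crop_richness ~ arm
    crop_richness ~~ garden_practices

``~`` declares a regression, ``~~`` a residual covariance; variables never
appearing on a left-hand side of ``~`` are exogenous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["PathModelSpec", "build_model_spec", "parse_model_syntax"]


@dataclass
class PathModelSpec:
    """Equations and residual structure of a recursive path model."""

    equations: dict  # dep -> list of regressor names (endogenous or exogenous)
    residual_blocks: list = field(default_factory=list)  # lists of endogenous names

    def __post_init__(self):
        self._validate()

    # -- derived structure -------------------------------------------------
    @property
    def endogenous(self):
        """Endogenous variables in topological order."""
        return self._topo_order()

    @property
    def exogenous(self):
        deps = set(self.equations)
        seen, out = set(), []
        for regs in self.equations.values():
            for r in regs:
                if r not in deps and r not in seen:
                    seen.add(r)
                    out.append(r)
        return out

    def blocks(self):
        """Residual blocks covering every endogenous variable (singletons added)."""
        covered = {v for b in self.residual_blocks for v in b}
        blocks = [list(b) for b in self.residual_blocks]
        for v in self.endogenous:
            if v not in covered:
                blocks.append([v])
        return blocks

    def n_free_parameters(self, mode: str, n_exog: int | None = None) -> int:
        m = len(self.endogenous)
        n_coef = sum(len(regs) for regs in self.equations.values())
        n_psi = sum(k * (k + 1) // 2 for k in (len(b) for b in self.blocks()))
        n = m + n_coef + n_psi  # intercepts + coefficients + residual block entries
        if mode == "saturated":
            p = len(self.exogenous) if n_exog is None else n_exog
            n += p + p * (p + 1) // 2
        return n

    # -- validation --------------------------------------------------------
    def _validate(self):
        deps = list(self.equations)
        if len(set(deps)) != len(deps):
            raise ValueError("duplicate dependent variable in equations")
        for dep, regs in self.equations.items():
            if len(set(regs)) != len(regs):
                raise ValueError(f"duplicate regressor in equation for {dep}")
            if dep in regs:
                raise ValueError(f"{dep} regressed on itself")
        self._topo_order()  # raises on cycles
        endo = set(self.equations)
        seen = set()
        for b in self.residual_blocks:
            for v in b:
                if v not in endo:
                    raise ValueError(f"residual block member {v!r} is not endogenous")
                if v in seen:
                    raise ValueError(f"{v!r} appears in two residual blocks")
                seen.add(v)

    def _topo_order(self):
        endo = set(self.equations)
        order, mark = [], {}

        def visit(v):
            if mark.get(v) == 1:
                raise ValueError(f"cyclic path specification at {v!r}")
            if mark.get(v) == 2:
                return
            mark[v] = 1
            for r in self.equations[v]:
                if r in endo:
                    visit(r)
            mark[v] = 2
            order.append(v)

        for v in self.equations:
            visit(v)
        return order


def build_model_spec(
    mediators,
    outcome,
    covariates,
    treatment="arm",
    market=None,
    market_feeders=None,
    residual_blocks=None,
    extra_mediators=(),
):
    """Default mediation spec: treatment -> mediators (a), treatment -> outcome
    (direct), mediators -> outcome (b), mediators -> market (d), covariates ->
    every endogenous variable.

    ``mediators`` excludes the market variable; pass ``market`` separately to
    add the sequential market pathway.  ``extra_mediators`` (e.g. empowerment
    indicators) get a- and b-paths but no d-paths.
    """
    mediators = list(mediators)
    extra = list(extra_mediators)
    covariates = list(covariates)
    eqs = {}
    for med in mediators + extra:
        eqs[med] = [treatment] + covariates
    all_meds = mediators + extra
    if market is not None:
        feeders = list(market_feeders) if market_feeders is not None else mediators
        eqs[market] = [treatment] + feeders + covariates
        all_meds = all_meds + [market]
    eqs[outcome] = [treatment] + all_meds + covariates
    if residual_blocks is None:
        residual_blocks = _default_blocks(mediators, extra)
    return PathModelSpec(equations=eqs, residual_blocks=residual_blocks)


def _default_blocks(mediators, extra):
    blocks = []
    gp = [m for m in mediators
          if m in ("crop_richness", "garden_practices", "n_poultry", "n_eggs")]
    kn = [m for m in mediators if m in ("fg_knowledge", "dd_knowledge")]
    if len(gp) > 1:
        blocks.append(gp)
    if len(kn) > 1:
        blocks.append(kn)
    if len(extra) > 1:
        blocks.append(list(extra))
    return blocks


def parse_model_syntax(text: str) -> PathModelSpec:
    """Parse the ``y ~ x1 + x2`` / ``m1 ~~ m2`` mini-language into a spec."""
    eqs: dict = {}
    pairs = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "~~" in line:
            lhs, rhs = (s.strip() for s in line.split("~~", 1))
            for r in rhs.split("+"):
                pairs.append((lhs, r.strip()))
        elif "~" in line:
            lhs, rhs = (s.strip() for s in line.split("~", 1))
            regs = [r.strip() for r in rhs.split("+") if r.strip()]
            eqs.setdefault(lhs, [])
            for r in regs:
                if r not in eqs[lhs]:
                    eqs[lhs].append(r)
        else:
            raise ValueError(f"line {lineno}: expected '~' or '~~' in {line!r}")
    blocks = _pairs_to_blocks(pairs)
    return PathModelSpec(equations=eqs, residual_blocks=blocks)


def _pairs_to_blocks(pairs):
    """Union declared covariance pairs into blocks (connected components)."""
    parent = {}

    def find(v):
        parent.setdefault(v, v)
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps: dict = {}
    for v in parent:
        comps.setdefault(find(v), []).append(v)
    return [sorted(c) for c in comps.values() if len(c) > 1]
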
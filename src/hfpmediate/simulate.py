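"""Synthetic cluster-randomized trial generator with known true effects.

Generates long-format panel records and a baseline covariate table with the
linear-Gaussian structure of the mediation DAG: treatment (settlement-level,
1:1), baseline covariates, seven mediators (market activity regressed on the
other six), and the woman-level dietary diversity outcome.  Because the true
path coefficients are configured, the implied direct/indirect decomposition is
known exactly, which is what makes parameter-recovery and interval-coverage
testing possible without the trial's raw data.

Generation is linear-Gaussian and by default does NOT truncate the dietary
diversity score to [0, 10]: the estimand is the linear path system, and
clamping would attenuate the configured effects.  A ``discretize_dds`` flag
produces integer food-group indicators instead, at the documented cost of
attenuation.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .mediation import DOMAINS
from .scores import FOOD_GROUP_COLUMNS

__all__ = [
    "GeneratorConfig",
    "TrueEffects",
    "generate_dataset",
    "impose_missingness",
    "implied_true_effects",
    "simulate_trial",
]


def _load_defaults() -> dict:
    with importlib.resources.files("hfpmediate").joinpath("defaults.yaml").open() as fh:
        return yaml.safe_load(fh)


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic trial; defaults from ``defaults.yaml``."""

    raw: dict = field(default_factory=_load_defaults)

    @classmethod
    def default(cls, **overrides) -> "GeneratorConfig":
        cfg = cls()
        cfg.raw.update(overrides)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        base = _load_defaults()
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        base.update(user)
        cfg = cls(raw=base)
        cfg.validate()
        return cfg

    def __getitem__(self, key):
        return self.raw[key]

    @property
    def mediators(self):
        return list(self.raw["mediators"])

    @property
    def market(self):
        return self.raw["market"]

    @property
    def outcome(self):
        return self.raw["outcome"]

    @property
    def endogenous(self):
        return self.mediators + [self.market, self.outcome]

    @property
    def covariate_names(self):
        return list(self.raw["covariates"].keys())

    def validate(self) -> None:
        alloc = self.raw["allocation"]
        if sum(alloc) != self.raw["n_clusters"]:
            raise ValueError("allocation must sum to n_clusters")
        for name, sd in self.raw["residual_sd"].items():
            if sd <= 0:
                raise ValueError(f"residual sd for {name} must be > 0")
        pattern = self.raw["missingness"]["diet_rounds"]
        if abs(sum(pattern.values()) - 1.0) > 1e-9:
            raise ValueError("diet-round missingness proportions must sum to 1")
        # residual blocks must be positive definite
        for block in self._psi_blocks()[0]:
            np.linalg.cholesky(block)

    def _psi_blocks(self, include_empowerment: bool = False):
        """Residual covariance blocks in endogenous order.

        Returns (blocks, names_per_block).  Blocks: the garden/poultry block
        (equicorrelated), the knowledge pair, then 1x1 blocks for market and
        the outcome (and an empowerment block when requested).
        """
        sd = self.raw["residual_sd"]
        rc = self.raw["residual_corr"]

        def equicorr(names, rho):
            s = np.array([sd[n] for n in names])
            k = len(s)
            r = np.full((k, k), rho) + (1 - rho) * np.eye(k)
            return r * np.outer(s, s)

        gp = ["crop_richness", "garden_practices", "n_poultry", "n_eggs"]
        kn = ["fg_knowledge", "dd_knowledge"]
        blocks = [equicorr(gp, rc["garden_poultry"]), equicorr(kn, rc["knowledge"])]
        names = [gp, kn]
        if include_empowerment:
            emp = self.raw.get("empowerment_mediators", {})
            enames = list(emp.keys())
            s = np.array([emp[n]["sd"] for n in enames])
            k = len(s)
            r = np.full((k, k), rc["empowerment"]) + (1 - rc["empowerment"]) * np.eye(k)
            blocks.append(r * np.outer(s, s))
            names.append(enames)
        blocks.append(np.array([[sd[self.market] ** 2]]))
        names.append([self.market])
        blocks.append(np.array([[sd[self.outcome] ** 2]]))
        names.append([self.outcome])
        return blocks, names

    def psi_matrix(self, include_empowerment: bool = False):
        """Full residual covariance over the endogenous variables (in order)."""
        blocks, names = self._psi_blocks(include_empowerment)
        order = [n for grp in names for n in grp]
        k = len(order)
        psi = np.zeros((k, k))
        i = 0
        for b in blocks:
            j = i + b.shape[0]
            psi[i:j, i:j] = b
            i = j
        # reorder to endogenous order
        endo = self.endogenous_with(include_empowerment)
        idx = [order.index(n) for n in endo]
        return psi[np.ix_(idx, idx)], endo

    def endogenous_with(self, include_empowerment: bool):
        meds = self.mediators[:]
        if include_empowerment:
            meds += list(self.raw.get("empowerment_mediators", {}).keys())
        return meds + [self.market, self.outcome]


@dataclass
class TrueEffects:
    """Closed-form effects implied by the configured path coefficients."""

    individual: dict          # mediator -> a*b
    via_market: dict          # mediator -> a*d*b_market
    market_alone: float       # a_market * b_market
    direct: float
    domains: dict             # domain sums, with and without market legs

    @property
    def sum_via_market(self):
        return sum(self.via_market.values())

    @property
    def total_indirect(self):
        return sum(self.individual.values()) + self.sum_via_market + self.market_alone

    @property
    def total(self):
        return self.direct + self.total_indirect


def implied_true_effects(config: GeneratorConfig) -> TrueEffects:
    """Exact products and sums of the configured true path coefficients."""
    tp = config["true_paths"]
    a, b, d = tp["a"], tp["b"], tp["d"]
    market = config.market
    meds = config.mediators
    individual = {m: a[m] * b[m] for m in meds}
    via_market = {m: a[m] * d[m] * b[market] for m in meds}
    market_alone = a[market] * b[market]
    domains = {}
    for dom, members in DOMAINS.items():
        domains[dom] = sum(individual[m] for m in members)
        domains[dom + "_with_market"] = domains[dom] + sum(via_market[m] for m in members)
    domains["market_activity"] = market_alone + sum(via_market.values())
    return TrueEffects(
        individual=individual,
        via_market=via_market,
        market_alone=market_alone,
        direct=tp["direct"],
        domains=domains,
    )


def _draw_covariates(config: GeneratorConfig, n: int, rng) -> pd.DataFrame:
    cols = {}
    for name, spec in config["covariates"].items():
        kind = spec["dist"]
        if kind == "bernoulli":
            cols[name] = rng.binomial(1, spec["p"], size=n).astype(float)
        elif kind == "normal":
            cols[name] = rng.normal(spec["mean"], spec["sd"], size=n)
        elif kind == "categorical":
            cols[name] = rng.choice(spec["levels"], p=spec["probs"], size=n).astype(float)
        else:
            raise ValueError(f"unknown covariate distribution {kind!r}")
    return pd.DataFrame(cols)


def _structural_matrices(config: GeneratorConfig, include_empowerment: bool):
    """True (B, Gamma, alpha) over endogenous order; Gamma covers [T, X]."""
    endo = config.endogenous_with(include_empowerment)
    covs = config.covariate_names
    tp = config["true_paths"]
    emp = config.raw.get("empowerment_mediators", {}) if include_empowerment else {}
    market, outcome = config.market, config.outcome
    m, p = len(endo), 1 + len(covs)
    B = np.zeros((m, m))
    G = np.zeros((m, p))
    idx = {v: i for i, v in enumerate(endo)}
    for med in config.mediators:
        G[idx[med], 0] = tp["a"][med]
        B[idx[market], idx[med]] = tp["d"][med]
        B[idx[outcome], idx[med]] = tp["b"][med]
    for name, espec in emp.items():
        G[idx[name], 0] = espec["a"]
        B[idx[outcome], idx[name]] = espec["b"]
    G[idx[market], 0] = tp["a"][market]
    B[idx[outcome], idx[market]] = tp["b"][market]
    G[idx[outcome], 0] = tp["direct"]
    for dep, loads in config["gamma"].items():
        for cov, val in loads.items():
            G[idx[dep], 1 + covs.index(cov)] = val

    # intercepts solved so the implied control-arm means hit the configured
    # targets: alpha = (I - B) m - Gamma [0, mu_x]
    means = dict(config["control_means"])
    for name, espec in emp.items():
        means[name] = espec["mean"]
    mvec = np.array([means[v] for v in endo])
    mu_x = np.zeros(p)
    for j, cov in enumerate(covs):
        spec = config["covariates"][cov]
        if spec["dist"] == "bernoulli":
            mu_x[1 + j] = spec["p"]
        elif spec["dist"] == "normal":
            mu_x[1 + j] = spec["mean"]
        else:
            mu_x[1 + j] = float(np.dot(spec["levels"], spec["probs"]))
    alpha = (np.eye(m) - B) @ mvec - G @ mu_x
    return B, G, alpha, endo


def generate_dataset(
    config: GeneratorConfig,
    seed: int,
    include_empowerment: bool = False,
):
    """Generate a complete (no missingness) synthetic trial.

    Returns ``(panel, baseline)``: a long-format panel DataFrame (one row per
    woman and diet round, with woman-level mediator measures carried on the
    round-1 row) and a baseline covariate table keyed by ``woman_id``.
    Cluster-level treatment assignment is balanced per ``allocation`` and
    independent of covariates.
    """
    rng = np.random.default_rng(seed)
    n_clusters = config["n_clusters"]
    alloc = config["allocation"]
    arm_by_cluster = rng.permutation(np.repeat([0, 1], alloc))
    sizes = np.maximum(1, rng.poisson(config["cluster_size_mean"], size=n_clusters))
    n = int(sizes.sum())

    cluster_id = np.repeat(np.arange(1, n_clusters + 1), sizes)
    arm = arm_by_cluster[cluster_id - 1]
    X = _draw_covariates(config, n, rng)
    B, G, alpha, endo = _structural_matrices(config, include_empowerment)
    m = len(endo)

    psi, _ = config.psi_matrix(include_empowerment)
    resid_sd_diag = np.sqrt(np.diag(psi))
    icc = config["icc"]
    sigma_u = resid_sd_diag * np.sqrt(icc / (1 - icc))

    zeta = rng.multivariate_normal(np.zeros(m), psi, size=n, method="cholesky")
    u_cluster = rng.normal(0.0, 1.0, size=(n_clusters, m)) * sigma_u
    shocks = zeta + u_cluster[cluster_id - 1]

    tx = np.column_stack([arm.astype(float), X.to_numpy(float)])
    eta = np.empty((n, m))
    base = alpha + tx @ G.T + shocks  # n x m
    for j in range(m):  # recursive order: B is strictly lower triangular
        eta[:, j] = base[:, j] + eta[:, :j] @ B[j, :j]

    woman_id = np.arange(1, n + 1)
    baseline = X.copy()
    baseline.insert(0, "woman_id", woman_id)

    y_idx = endo.index(config.outcome)
    n_rounds = config["n_diet_rounds"]
    round_sd = config["round_noise_sd"]
    round_dates = ["2018-03-15", "2018-09-15", "2019-03-15", "2019-09-15"]
    ramadan = rng.binomial(1, config["ramadan_prob"], size=(n, n_rounds))
    round_noise = rng.normal(0.0, round_sd, size=(n, n_rounds)) if round_sd > 0 else np.zeros((n, n_rounds))
    dds_rounds = eta[:, [y_idx]] + round_noise

    panel = pd.DataFrame({
        "woman_id": np.repeat(woman_id, n_rounds),
        "cluster_id": np.repeat(cluster_id, n_rounds),
        "arm": np.repeat(arm, n_rounds),
        "round_index": np.tile(np.arange(1, n_rounds + 1), n),
        "round_date": np.tile(np.array(round_dates[:n_rounds]), n),
        "ramadan": ramadan.reshape(-1),
        "dds": dds_rounds.reshape(-1),
    })
    if config["discretize_dds"]:
        k = np.clip(np.rint(panel["dds"].to_numpy()), 0, 10).astype(int)
        fg = np.zeros((len(k), 10))
        for i, ki in enumerate(k):
            fg[i, rng.choice(10, size=ki, replace=False)] = 1.0
        for j, c in enumerate(FOOD_GROUP_COLUMNS):
            panel[c] = fg[:, j]
        panel = panel.drop(columns=["dds"])

    # woman-level measures carried on the round-1 rows
    first = panel["round_index"] == 1
    measure_cols = {
        "crop_richness": "crop_species_harvested",
        "garden_practices": "garden_practices_score",
        "n_poultry": "n_poultry",
        "n_eggs": "n_eggs_week",
        "fg_knowledge": "fg_knowledge_score",
        "dd_knowledge": "dd_knowledge_score",
        config.market: "market_score",
    }
    emp_names = [v for v in endo if v.startswith("emp_end_")]
    for v in emp_names:
        measure_cols[v] = v
    for var, col in measure_cols.items():
        panel[col] = np.nan
        panel.loc[first, col] = eta[:, endo.index(var)]
    return panel, baseline


def impose_missingness(panel: pd.DataFrame, config: GeneratorConfig, seed: int) -> pd.DataFrame:
    """Apply the configured MCAR missingness to a complete panel.

    Per woman, the number of observed diet rounds is drawn from the
    configured pattern over {4, 3, 2, 1} and the remaining rounds' diet
    observations are blanked; each mediator measure is independently blanked
    (all rounds) at its configured per-variable rate.
    """
    pattern = config["missingness"]["diet_rounds"]
    if abs(sum(pattern.values()) - 1.0) > 1e-9:
        raise ValueError("diet-round proportions must sum to 1")
    rng = np.random.default_rng(seed)
    panel = panel.sort_values(["woman_id", "round_index"]).reset_index(drop=True)
    women = panel["woman_id"].unique()
    n_rounds = int(panel["round_index"].max())
    counts = np.array(sorted(pattern.keys(), reverse=True))
    probs = np.array([pattern[k] for k in counts], dtype=float)
    k_obs = rng.choice(counts, p=probs, size=len(women))

    diet_cols = [c for c in ["dds"] + FOOD_GROUP_COLUMNS if c in panel.columns]
    drop_mask = np.zeros(len(panel), dtype=bool)
    for i in range(len(women)):
        k = k_obs[i]
        if k >= n_rounds:
            continue
        dropped = rng.choice(n_rounds, size=n_rounds - k, replace=False)
        drop_mask[i * n_rounds + dropped] = True
    panel.loc[drop_mask, diet_cols] = np.nan

    var_cols = {
        "crop_richness": "crop_species_harvested",
        "garden_practices": "garden_practices_score",
        "n_poultry": "n_poultry",
        "n_eggs": "n_eggs_week",
        "fg_knowledge": "fg_knowledge_score",
        "dd_knowledge": "dd_knowledge_score",
        "market_score": "market_score",
    }
    for var, rate in config["missingness"].get("variables", {}).items():
        col = var_cols.get(var, var)
        if col not in panel.columns or rate <= 0:
            continue
        hit = rng.random(len(women)) < rate
        mask = np.repeat(hit, n_rounds)
        panel.loc[mask, col] = np.nan
    return panel


def simulate_trial(config: GeneratorConfig, seed: int, missingness: bool = True,
                   include_empowerment: bool = False):
    """Generate a trial and (optionally) apply the configured missingness."""
    panel, baseline = generate_dataset(config, seed, include_empowerment)
    if missingness:
        panel = impose_missingness(panel, config, seed + 1)
    return panel, baseline
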
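"""Woman-level score construction from long-format panel records.

The surveillance system records, for each woman and survey round, a 24-hour
dietary recall (10 binary food-group indicators), garden and poultry measures,
knowledge batteries and market-activity indicators.  This module turns those
per-round records into the one-row-per-woman analysis table used by the total
effect and mediation models:

* ``dds`` — dietary diversity score, the number of the 10 food groups consumed
  in the prior 24 h (0-10);
* ``mdd`` — minimum dietary diversity, met when at least 5 of the 10 groups
  were consumed; aggregated per woman as the proportion of observed diet
  rounds in which it was met;
* mediator scores (crop species richness, garden practices, poultry and egg
  counts, knowledge sums, market-activity sum) averaged over the rounds in
  which they were observed.

Missing-data conventions: an empty CSV cell is "absent"; a food-group recall
is absent as a whole block (all 10 indicators missing together); a woman with
no diet observation at all is excluded from the analysis table; every other
absence is kept as NaN and handled downstream by full-information maximum
likelihood.

Panel CSV schema (long format, one row per woman and survey round)::

    woman_id, cluster_id, arm, round_index, round_date (ISO-8601), ramadan,
    fg_1..fg_10            10 binary food-group indicators (or a `dds` column
                           with the precomputed round score),
    crop_species_harvested, garden_practices_score, n_poultry, n_eggs_week,
    ddk_1..ddk_4           diet-diversity knowledge items (or
                           dd_knowledge_score),
    fgk_1..fgk_5           food-group knowledge items (or fg_knowledge_score),
    market_bought, market_sold, market_went  (or market_score)

Baseline CSV: one row per woman_id with the covariate columns listed in
:data:`BASELINE_COLUMNS`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MDD_THRESHOLD = 5
N_FOOD_GROUPS = 10
MAX_DIET_ROUNDS = 4

FOOD_GROUP_COLUMNS = [f"fg_{i}" for i in range(1, N_FOOD_GROUPS + 1)]
DD_KNOWLEDGE_COLUMNS = [f"ddk_{i}" for i in range(1, 5)]
FG_KNOWLEDGE_COLUMNS = [f"fgk_{i}" for i in range(1, 6)]
MARKET_COLUMNS = ["market_bought", "market_sold", "market_went"]

#: per-round measure columns averaged into woman-level means
MEASURE_COLUMNS = {
    "crop_species_harvested": "crop_richness",
    "garden_practices_score": "garden_practices",
    "n_poultry": "n_poultry",
    "n_eggs_week": "n_eggs",
}

BASELINE_COLUMNS = [
    "religion_muslim",
    "wealth_quintile",
    "log_homestead_land",
    "log_agri_land",
    "crop_richness_baseline",
    "market_score_baseline",
    "education",
    "emp_social_support",
    "emp_comm_husband",
    "emp_external_comm",
    "emp_decision",
    "emp_mobility",
    "emp_income",
    "dds_baseline",
]


class MissingMeasure(Exception):
    """Signals that a round contributes no observation for a measure."""


def _is_absent(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def compute_dds(food_groups) -> int:
    """Dietary diversity score: integer sum of the 10 food-group indicators.

    Raises :class:`MissingMeasure` if any indicator is absent (the whole
    recall is treated as missing for that round) and ``ValueError`` if an
    indicator is not 0/1.
    """
    fg = list(food_groups)
    if len(fg) != N_FOOD_GROUPS:
        raise ValueError(f"expected {N_FOOD_GROUPS} food-group indicators, got {len(fg)}")
    if any(_is_absent(v) for v in fg):
        raise MissingMeasure("food-group recall absent for this round")
    vals = [float(v) for v in fg]
    if any(v not in (0.0, 1.0) for v in vals):
        raise ValueError(f"non-binary food-group indicator in {fg}")
    return int(sum(vals))


def met_mdd(dds) -> int:
    """1 if the score meets minimum dietary diversity (>= 5 of 10 groups)."""
    if _is_absent(dds):
        raise MissingMeasure("dietary diversity score absent")
    if not 0 <= dds <= N_FOOD_GROUPS:
        raise ValueError(f"dietary diversity score {dds} outside [0, {N_FOOD_GROUPS}]")
    return int(dds >= MDD_THRESHOLD)


def build_market_score(bought, sold, went) -> int:
    """Market-activity sum score 0-3: bought goods, sold goods, went to market."""
    vals = (bought, sold, went)
    if any(_is_absent(v) for v in vals):
        raise MissingMeasure("market-activity indicator absent")
    vals = tuple(float(v) for v in vals)
    if any(v not in (0.0, 1.0) for v in vals):
        raise ValueError(f"non-binary market indicator in {vals}")
    return int(sum(vals))


def aggregate_woman_rounds(values, ramadan=None, drop_ramadan: bool = False):
    """Mean of a per-round measure over the rounds where it was observed.

    Parameters
    ----------
    values : sequence
        Per-round values; ``None``/NaN marks an absent round.
    ramadan : sequence of bool, optional
        Per-round Ramadan flags, aligned with ``values``.
    drop_ramadan : bool
        If True, rounds flagged as Ramadan are excluded before averaging
        (sensitivity analysis for fasting-period diets).

    Returns
    -------
    (mean, n_rounds) : tuple
        Mean over contributing rounds and their count.

    Raises
    ------
    MissingMeasure
        If no round contributes after exclusions.
    """
    vals = list(values)
    flags = [False] * len(vals) if ramadan is None else [bool(f) for f in ramadan]
    if len(flags) != len(vals):
        raise ValueError("ramadan flags must align with values")
    kept = [float(v) for v, f in zip(vals, flags)
            if not _is_absent(v) and not (drop_ramadan and f)]
    if not kept:
        raise MissingMeasure("no observed rounds for this measure")
    return sum(kept) / len(kept), len(kept)


def _knowledge_score(row: pd.Series, item_cols, score_col, woman_id):
    """Sum of correct battery items; partial batteries are treated as missing."""
    present = [c for c in item_cols if c in row.index and not _is_absent(row[c])]
    if present:
        if len(present) < len(item_cols):
            logger.warning(
                "woman %s: partially answered battery %s (%d/%d items); score set missing",
                woman_id, score_col, len(present), len(item_cols),
            )
            return np.nan
        return float(sum(float(row[c]) for c in item_cols))
    if score_col in row.index and not _is_absent(row[score_col]):
        return float(row[score_col])
    return np.nan


@dataclass
class AssembleOptions:
    """Options for analysis-table assembly."""

    drop_ramadan: bool = False
    max_diet_rounds: int = MAX_DIET_ROUNDS
    require_baseline: bool = True
    extra_measures: tuple = ()   # extra per-round columns averaged per woman


@dataclass
class AssemblyLog:
    n_input_women: int = 0
    n_retained: int = 0
    excluded_no_diet: list = field(default_factory=list)


def _round_dds(row: pd.Series):
    """Round-level DDS from indicators if present, else a ``dds`` column."""
    fg_cols = [c for c in FOOD_GROUP_COLUMNS if c in row.index]
    if fg_cols and not all(_is_absent(row[c]) for c in fg_cols):
        return float(compute_dds([row.get(c, np.nan) for c in FOOD_GROUP_COLUMNS]))
    if "dds" in row.index and not _is_absent(row["dds"]):
        return float(row["dds"])
    raise MissingMeasure("no diet observation this round")


def assemble_analysis_table(
    panel: pd.DataFrame,
    baseline: pd.DataFrame,
    options: AssembleOptions | None = None,
):
    """Build the one-row-per-woman analysis table from panel records.

    ``panel`` is long format, one row per (woman_id, round_index), with the
    columns documented in this module; ``baseline`` is keyed by ``woman_id``.
    Women with no diet observation in any round are excluded (they provide no
    outcome data); every other absence is carried forward as NaN for the
    likelihood to handle.

    Returns ``(table, log)`` where ``table`` is a DataFrame indexed 0..n-1
    and ``log`` an :class:`AssemblyLog`.
    """
    opts = options or AssembleOptions()
    if panel.duplicated(subset=["woman_id", "round_index"]).any():
        dup = panel[panel.duplicated(subset=["woman_id", "round_index"])].iloc[0]
        raise ValueError(
            f"duplicate panel record for woman {dup['woman_id']} round {dup['round_index']}"
        )
    baseline = baseline.set_index("woman_id") if "woman_id" in baseline.columns else baseline
    if baseline.index.duplicated().any():
        raise ValueError("duplicate woman_id in baseline table")

    rows = []
    log = AssemblyLog()
    for woman_id, grp in panel.groupby("woman_id", sort=True):
        log.n_input_women += 1
        if woman_id not in baseline.index:
            if opts.require_baseline:
                raise KeyError(f"woman {woman_id} missing from baseline table")
            continue
        if grp["cluster_id"].nunique() != 1:
            raise ValueError(f"woman {woman_id}: cluster_id varies across rounds")
        if grp["arm"].nunique() != 1:
            raise ValueError(f"woman {woman_id}: arm varies across rounds")

        grp = grp.sort_values("round_index")
        diet = []
        for _, r in grp.iterrows():
            try:
                diet.append(_round_dds(r))
            except MissingMeasure:
                diet.append(np.nan)
        n_diet = sum(0 if math.isnan(d) else 1 for d in diet)
        if n_diet > opts.max_diet_rounds:
            raise ValueError(
                f"woman {woman_id}: {n_diet} diet rounds exceeds the "
                f"{opts.max_diet_rounds}-round assessment design"
            )
        flags = [bool(f) and not _is_absent(f) for f in grp.get("ramadan", pd.Series(False, index=grp.index))]
        try:
            dds_mean, n_rounds = aggregate_woman_rounds(diet, flags, opts.drop_ramadan)
            # threshold directly: synthetic untruncated scores may fall
            # outside [0, 10], which the strict met_mdd validator rejects
            mdd_vals = [float(d >= MDD_THRESHOLD) if not math.isnan(d) else np.nan
                        for d in diet]
            mdd_prop, _ = aggregate_woman_rounds(mdd_vals, flags, opts.drop_ramadan)
        except MissingMeasure:
            log.excluded_no_diet.append(woman_id)
            continue

        row = {
            "woman_id": woman_id,
            "cluster_id": grp["cluster_id"].iloc[0],
            "arm": int(grp["arm"].iloc[0]),
            "dds_mean": dds_mean,
            "mdd_prop": mdd_prop,
            "n_diet_rounds": n_rounds,
        }
        measures = dict(MEASURE_COLUMNS)
        measures.update({c: c for c in opts.extra_measures})
        for src, dst in measures.items():
            if src in grp.columns:
                try:
                    row[dst], _ = aggregate_woman_rounds(grp[src].tolist())
                except MissingMeasure:
                    row[dst] = np.nan
            else:
                row[dst] = np.nan

        # knowledge and market measures: observed at one or two time points,
        # treated as round-invariant woman-level values
        first = _first_observed_row(grp, DD_KNOWLEDGE_COLUMNS + ["dd_knowledge_score"])
        row["dd_knowledge"] = (
            _knowledge_score(first, DD_KNOWLEDGE_COLUMNS, "dd_knowledge_score", woman_id)
            if first is not None else np.nan
        )
        first = _first_observed_row(grp, FG_KNOWLEDGE_COLUMNS + ["fg_knowledge_score"])
        row["fg_knowledge"] = (
            _knowledge_score(first, FG_KNOWLEDGE_COLUMNS, "fg_knowledge_score", woman_id)
            if first is not None else np.nan
        )
        row["market_score"] = _market_from_rounds(grp)

        for c in BASELINE_COLUMNS:
            row[c] = baseline.loc[woman_id, c] if c in baseline.columns else np.nan
        rows.append(row)
        log.n_retained += 1

    table = pd.DataFrame(rows).reset_index(drop=True)
    logger.info(
        "analysis table: %d women retained of %d (%d excluded with no diet data)",
        log.n_retained, log.n_input_women, len(log.excluded_no_diet),
    )
    return table, log


def _first_observed_row(grp: pd.DataFrame, cols):
    cols = [c for c in cols if c in grp.columns]
    if not cols:
        return None
    mask = grp[cols].notna().any(axis=1)
    if not mask.any():
        return None
    return grp.loc[mask].iloc[0]


def _market_from_rounds(grp: pd.DataFrame):
    have_items = all(c in grp.columns for c in MARKET_COLUMNS)
    if have_items:
        mask = grp[MARKET_COLUMNS].notna().all(axis=1)
        if mask.any():
            r = grp.loc[mask].iloc[0]
            return float(build_market_score(*[r[c] for c in MARKET_COLUMNS]))
    if "market_score" in grp.columns:
        obs = grp["market_score"].dropna()
        if len(obs):
            return float(obs.iloc[0])
    return np.nan
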
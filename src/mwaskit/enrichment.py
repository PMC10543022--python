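"""Pathway over-representation of metabolite hit sets.

Hits are tested against the classified-metabolite universe (metabolites
carrying a pathway annotation) with a two-sided Fisher exact test on the
2x2 table (hit/non-hit x in-pathway/not), separately for super- and
sub-pathway levels.  Raw p-values are the primary output; BH q-values
across pathways within a level are reported alongside.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_fdr
from .datatypes import validate_annotation

logger = logging.getLogger("mwaskit")

ENRICHMENT_COLUMNS = (
    "pathway",
    "level",
    "a",
    "b",
    "c",
    "d",
    "odds_ratio",
    "pvalue",
    "qvalue",
)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test (minimum-likelihood convention).

    Returns (odds ratio, p-value); the convention sums the probabilities of
    all tables with the observed margins no more likely than the observed
    one.
    """
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


def fisher_enrichment(
    hits,
    ann: pd.DataFrame,
    direction: str = "all",
    betas: pd.Series | None = None,
) -> pd.DataFrame:
    """Test every pathway for over-representation of the hit set.

    Parameters
    ----------
    hits
        Metabolite ids of the hit set; intersected with the classified
        universe before testing.
    ann
        Pathway annotation table (metabolite_id, super_pathway, sub_pathway).
    direction
        ``all`` uses the hit set as given; ``up``/``down`` first restricts it
        by the sign of ``betas``.
    betas
        Per-metabolite effect estimates, required for ``up``/``down``.
    """
    validate_annotation(ann)
    hits = pd.Index(pd.unique(pd.Series(list(hits), dtype=object)))
    if direction not in ("all", "up", "down"):
        raise ValueError(f"unknown direction {direction!r}")
    if direction != "all":
        if betas is None:
            raise ValueError("direction-specific enrichment needs betas")
        sign = 1 if direction == "up" else -1
        hits = hits[np.sign(betas.reindex(hits)) == sign]

    classified = ann[ann["super_pathway"].notna()]
    universe = pd.Index(classified["metabolite_id"].unique())
    hit_set = hits.intersection(universe)
    if len(hit_set) == 0:
        logger.warning("no classified hits; enrichment table is empty")
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)

    rows = []
    for level, col in (("super", "super_pathway"), ("sub", "sub_pathway")):
        ann_level = classified[classified[col].notna()]
        for pathway, members in ann_level.groupby(col)["metabolite_id"]:
            in_path = pd.Index(members.unique())
            a = len(hit_set.intersection(in_path))
            b = len(hit_set) - a
            c = len(in_path) - a
            d = len(universe) - a - b - c
            odds, p = fisher_exact_2x2(a, b, c, d)
            rows.append(
                {"pathway": pathway, "level": level, "a": a, "b": b, "c": c, "d": d,
                 "odds_ratio": odds, "pvalue": p}
            )
    table = pd.DataFrame(rows)
    table["qvalue"] = np.nan
    for level in ("super", "sub"):
        sel = table["level"] == level
        if sel.any():
            table.loc[sel, "qvalue"] = bh_fdr(table.loc[sel, "pvalue"].to_numpy())
    return table.sort_values(["level", "pvalue"]).reset_index(drop=True)


__all__ = ["fisher_enrichment", "fisher_exact_2x2", "ENRICHMENT_COLUMNS"]
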
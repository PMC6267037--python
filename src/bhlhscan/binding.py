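"""DNA-binding classification from basic-region residues.

The rules are positional, 1-based within the located domain (position 1 is
the first basic-region residue):

* a basic region with at least five basic residues (Arg/Lys/His) marks a
  DNA binder;
* Glu-13 together with Arg-16 marks E-box recognition;
* His or Lys at 9 together with Arg-17, on top of the E-box pair, marks
  G-box recognition (the G-box being a specific E-box type);
* domains below the five-basic-residue bar that nevertheless carry the full
  E-box or G-box residue set are rescued as "potential" binders.

This yields six mutually exclusive categories matching the family-table
layout: G binder, E non G, non E binder (the three DNA-binder columns),
E-box, G-box (the two potential-binder columns) and non DNA binder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from sklearn.base import BaseEstimator

from ._util import AMINO_ACIDS
from .scan import RegionTemplate

log = logging.getLogger(__name__)

BASIC_RESIDUES = frozenset("RKH")

CATEGORIES = (
    "G_binder",
    "E_non_G",
    "non_E_binder",
    "potential_E_box",
    "potential_G_box",
    "non_binder",
)

# printed column names of the family table, in table order
PRINTED_NAMES = {
    "G_binder": "G binder",
    "E_non_G": "E non G",
    "non_E_binder": "non E binder",
    "potential_E_box": "E-box",
    "potential_G_box": "G-box",
    "non_binder": "non DNA binder",
}
TABLE_COLUMNS = [PRINTED_NAMES[c] for c in CATEGORIES] + ["Total"]

DNA_BINDER_CATEGORIES = frozenset({"G_binder", "E_non_G", "non_E_binder"})
E_BOX_CATEGORIES = frozenset({"G_binder", "E_non_G"})


@dataclass
class BindingCall:
    """Per-domain binding category with the residue evidence behind it."""

    protein_id: str
    basic_count: int
    has_E13: bool
    has_R16: bool
    has_HK9: bool
    has_R17: bool
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown binding category {self.category!r}")


def count_basic_residues(
    basic_region: str, expected_length: int = 17, protein_id: str = "?"
) -> int:
    """Count Arg/Lys/His in the basic region (default 17 residues)."""
    if len(basic_region) < expected_length:
        raise ValueError(
            f"basic region of {protein_id!r} has {len(basic_region)} residues, "
            f"expected at least {expected_length}"
        )
    return sum(1 for ch in basic_region[:expected_length] if ch in BASIC_RESIDUES)


def _rule_residue(domain: str, position: int, protein_id: str) -> str:
    ch = domain[position - 1]
    if ch not in AMINO_ACIDS:
        log.warning(
            "non-standard residue %r at rule position %d of %s; treated as non-match",
            ch, position, protein_id,
        )
    return ch


def classify_binding(
    domain_sequence: str,
    region_template: RegionTemplate | None = None,
    protein_id: str = "?",
    min_basic: int = 5,
) -> BindingCall:
    """Classify one located domain sequence into the six binding categories."""
    tpl = region_template or RegionTemplate()
    domain_sequence = domain_sequence.upper()
    if len(domain_sequence) < tpl.basic:
        raise ValueError(
            f"domain of {protein_id!r} shorter than the basic region "
            f"({len(domain_sequence)} < {tpl.basic})"
        )
    basic_count = count_basic_residues(domain_sequence, tpl.basic, protein_id)
    has_e13 = _rule_residue(domain_sequence, 13, protein_id) == "E"
    has_r16 = _rule_residue(domain_sequence, 16, protein_id) == "R"
    has_hk9 = _rule_residue(domain_sequence, 9, protein_id) in {"H", "K"}
    has_r17 = _rule_residue(domain_sequence, 17, protein_id) == "R"

    e_box = has_e13 and has_r16
    g_box_extra = has_hk9 and has_r17
    if basic_count >= min_basic:
        if e_box:
            category = "G_binder" if g_box_extra else "E_non_G"
        else:
            category = "non_E_binder"
    else:
        if e_box and g_box_extra:
            category = "potential_G_box"
        elif e_box:
            category = "potential_E_box"
        else:
            category = "non_binder"
    return BindingCall(
        protein_id=protein_id,
        basic_count=basic_count,
        has_E13=has_e13,
        has_R16=has_r16,
        has_HK9=has_hk9,
        has_R17=has_r17,
        category=category,
    )


def tabulate_categories(calls: list[BindingCall], species_of: dict[str, str]) -> pd.DataFrame:
    """Species x category contingency table with Total column and grand-total
    row, in the printed column layout."""
    missing = [c.protein_id for c in calls if c.protein_id not in species_of]
    if missing:
        raise ValueError(f"no species label for: {missing[:5]}")
    species = sorted(set(species_of[c.protein_id] for c in calls))
    table = pd.DataFrame(0, index=species, columns=TABLE_COLUMNS, dtype=int)
    for call in calls:
        table.loc[species_of[call.protein_id], PRINTED_NAMES[call.category]] += 1
    table["Total"] = table[[PRINTED_NAMES[c] for c in CATEGORIES]].sum(axis=1)
    table.loc["Total"] = table.sum(axis=0)
    table.index.name = "species"
    return table


def derive_aggregates(table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate groups per species: DNA binders (>=5 basic residues),
    E-box binders (Glu-13 + Arg-16 among them), G-box binders, and the
    non-binder group (potential E/G plus non DNA binders)."""
    out = pd.DataFrame(index=table.index)
    out["dna_binders"] = (
        table["G binder"] + table["E non G"] + table["non E binder"]
    )
    out["e_box_binders"] = table["G binder"] + table["E non G"]
    out["g_box_binders"] = table["G binder"]
    out["non_binder_group"] = (
        table["E-box"] + table["G-box"] + table["non DNA binder"]
    )
    out.index.name = table.index.name
    return out


class BindingRuleClassifier(BaseEstimator):
    """Stateless estimator over the residue rules: predict(X) maps domain
    sequences to category labels; predict_calls returns full evidence."""

    def __init__(self, min_basic: int = 5, region_template: RegionTemplate | None = None):
        self.min_basic = min_basic
        self.region_template = region_template

    def fit(self, X=None, y=None):
        self.is_fitted_ = True
        return self

    def predict_calls(self, X: list[str], ids: list[str] | None = None) -> list[BindingCall]:
        ids = ids or [f"seq{i}" for i in range(len(X))]
        return [
            classify_binding(seq, self.region_template, pid, self.min_basic)
            for seq, pid in zip(X, ids)
        ]

    def predict(self, X: list[str]) -> list[str]:
        return [c.category for c in self.predict_calls(X)]
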
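"""Taxonomic-conservation classification of orthogroups.

Orthogroups inferred across 11 bee datasets (nine NCBI proteomes plus the
two study transcriptomes) are assigned to conservation categories from
their presence/absence pattern alone: from "apinae" (present in every
dataset, including the Habropoda laboriosa outgroup) down to
"species-specific" (present in a single focal transcriptome). Rules are
data, not code: a rule is an ordered list of predicates over datasets and
named clades, evaluated first-match-wins with a guaranteed "other"
catch-all, so contested category boundaries can be edited without touching
the engine.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .io_core import OrthogroupMatrix, logger

# Dataset ids for the 11 inputs of the original comparison.
OUTGROUP = "H_laboriosa"
ORCHID_BEES = ("E_dilemma", "E_mexicana")
BUMBLEBEES = ("B_impatiens", "B_terrestris_genome", "B_terrestris_transcriptome")
HONEYBEES = ("A_cerana", "A_mellifera")
STINGLESS_BEES = ("F_varia", "M_quadrifasciata", "T_angustula_transcriptome")

DEFAULT_DATASETS: tuple[str, ...] = (
    (OUTGROUP,) + ORCHID_BEES + BUMBLEBEES + HONEYBEES + STINGLESS_BEES
)

DEFAULT_CLADES: dict[str, set[str]] = {
    "outgroup": {OUTGROUP},
    "orchid_bees": set(ORCHID_BEES),
    "bumblebees": set(BUMBLEBEES),
    "honeybees": set(HONEYBEES),
    "stingless_bees": set(STINGLESS_BEES),
}


@dataclass(frozen=True)
class CategoryRule:
    """One category predicate. Clause values may be dataset ids or clade names.

    - ``present_in_all``: every listed dataset/clade member has the orthogroup
    - ``present_in_any_of_each``: for each listed clade, at least one member
      has it (the "present in all corbiculate lineages" reading)
    - ``present_in_any``: at least one listed dataset/clade member has it
    - ``absent_from_all``: no listed dataset/clade member has it
    - ``ignore``: datasets whose state is irrelevant for the absent-elsewhere
      closure (e.g. F. varia in the relaxed stingless-bee class)
    - ``exclusive``: if true, the orthogroup must be absent from every dataset
      not referenced by the present_* clauses (minus ``ignore``)
    """

    name: str
    present_in_all: tuple[str, ...] = ()
    present_in_any_of_each: tuple[str, ...] = ()
    present_in_any: tuple[str, ...] = ()
    absent_from_all: tuple[str, ...] = ()
    ignore: tuple[str, ...] = ()
    exclusive: bool = False


def _expand(names: tuple[str, ...], clades: dict[str, set[str]],
            datasets: set[str]) -> set[str]:
    out: set[str] = set()
    for n in names:
        if n in clades:
            out |= clades[n]
        elif n in datasets:
            out.add(n)
        else:
            raise KeyError(f"unknown dataset or clade {n!r}")
    return out


# Shipped default interpretation of the eight published categories (plus the
# catch-all). Most-conserved first; first match wins.
DEFAULT_RULES: tuple[CategoryRule, ...] = (
    CategoryRule("apinae", present_in_all=("outgroup", "orchid_bees", "bumblebees",
                                           "honeybees", "stingless_bees")),
    CategoryRule("corbiculates",
                 present_in_any_of_each=("orchid_bees", "bumblebees", "honeybees",
                                         "stingless_bees"),
                 absent_from_all=("outgroup",)),
    CategoryRule("social_corbiculates",
                 present_in_any_of_each=("bumblebees", "honeybees", "stingless_bees"),
                 absent_from_all=("outgroup", "orchid_bees")),
    CategoryRule("bumblebees",
                 present_in_all=("B_impatiens",),
                 present_in_any=("B_terrestris_genome", "B_terrestris_transcriptome"),
                 exclusive=True),
    CategoryRule("stingless_bees_f",
                 present_in_all=("F_varia", "M_quadrifasciata", "T_angustula_transcriptome"),
                 exclusive=True),
    CategoryRule("stingless_bees",
                 present_in_all=("M_quadrifasciata", "T_angustula_transcriptome"),
                 ignore=("F_varia",),
                 exclusive=True),
    CategoryRule("bterrestris_g",
                 present_in_all=("B_terrestris_transcriptome", "B_terrestris_genome"),
                 exclusive=True),
    CategoryRule("species_specific_bterrestris",
                 present_in_all=("B_terrestris_transcriptome",),
                 exclusive=True),
    CategoryRule("species_specific_tangustula",
                 present_in_all=("T_angustula_transcriptome",),
                 exclusive=True),
)

OTHER_CATEGORY = "other"

#: The three conserved classes, for "restricted vs conserved" summaries.
CONSERVED_CATEGORIES = ("apinae", "corbiculates", "social_corbiculates")


@dataclass
class CategoryReport:
    """Counts and proportions per category for the transcriptome-wide ring
    and the focal (DE-associated) ring, plus the unassigned-gene audit."""

    categories: list[str]
    transcriptome_counts: dict[str, int]
    transcriptome_proportions: dict[str, float]
    focal_counts: dict[str, int]
    focal_proportions: dict[str, float]
    n_transcriptome: int
    n_focal: int
    audit: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.categories:
            rows.append({
                "category": c,
                "transcriptome_count": self.transcriptome_counts.get(c, 0),
                "transcriptome_proportion": self.transcriptome_proportions.get(c, 0.0),
                "focal_count": self.focal_counts.get(c, 0),
                "focal_proportion": self.focal_proportions.get(c, 0.0),
            })
        return pd.DataFrame(rows)


def load_clades(path: str | Path) -> dict[str, set[str]]:
    """Load a clade -> dataset-id mapping from a TOML file ([clades] table)."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    table = data.get("clades", data)
    return {name: set(members) for name, members in table.items()}


def load_rules(path: str | Path) -> tuple[CategoryRule, ...]:
    """Load an ordered rule list from a TOML file ([[rules]] array)."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    rules = []
    for entry in data["rules"]:
        rules.append(CategoryRule(
            name=entry["name"],
            present_in_all=tuple(entry.get("present_in_all", ())),
            present_in_any_of_each=tuple(entry.get("present_in_any_of_each", ())),
            present_in_any=tuple(entry.get("present_in_any", ())),
            absent_from_all=tuple(entry.get("absent_from_all", ())),
            ignore=tuple(entry.get("ignore", ())),
            exclusive=bool(entry.get("exclusive", False)),
        ))
    return tuple(rules)


def _matches(rule: CategoryRule, present: set[str], datasets: set[str],
             clades: dict[str, set[str]]) -> bool:
    referenced: set[str] = set()
    req_all = _expand(rule.present_in_all, clades, datasets)
    referenced |= req_all
    if not req_all <= present:
        return False
    for clade_name in rule.present_in_any_of_each:
        members = _expand((clade_name,), clades, datasets)
        referenced |= members
        if not members & present:
            return False
    if rule.present_in_any:
        members = _expand(rule.present_in_any, clades, datasets)
        referenced |= members
        if not members & present:
            return False
    if rule.absent_from_all:
        members = _expand(rule.absent_from_all, clades, datasets)
        if members & present:
            return False
    if rule.exclusive:
        ignored = _expand(rule.ignore, clades, datasets)
        if (present - referenced) - ignored:
            return False
    return True


def classify_orthogroup(presence: dict[str, bool],
                        rules: tuple[CategoryRule, ...] = DEFAULT_RULES,
                        clades: dict[str, set[str]] | None = None) -> str:
    """Assign one presence/absence pattern to exactly one category.

    ``presence`` must be indexed by every expected dataset id; the first
    matching rule (in priority order) wins and the catch-all "other" is
    returned when nothing matches.
    """
    clades = clades if clades is not None else DEFAULT_CLADES
    datasets = set(presence)
    known = set().union(*clades.values()) if clades else set()
    # every pattern key must be resolvable through a clade or a rule mention
    for d in datasets:
        if d not in known and not any(
            d in (r.present_in_all + r.present_in_any + r.absent_from_all + r.ignore)
            for r in rules
        ):
            raise KeyError(f"unknown dataset id {d!r} in presence pattern")
    present = {d for d, p in presence.items() if p}
    for rule in rules:
        if _matches(rule, present, datasets, clades):
            return rule.name
    return OTHER_CATEGORY


def classify_matrix(matrix: OrthogroupMatrix,
                    rules: tuple[CategoryRule, ...] = DEFAULT_RULES,
                    clades: dict[str, set[str]] | None = None) -> dict[str, str]:
    """Classify every orthogroup in a matrix; returns orthogroup -> category."""
    present_df = matrix.counts > 0
    out: dict[str, str] = {}
    for og in matrix.orthogroup_ids:
        presence = present_df.loc[og].to_dict()
        out[og] = classify_orthogroup(presence, rules, clades)
    return out


def exclude_unassigned(matrix: OrthogroupMatrix, dataset: str,
                       focal_genes: "list[str] | set[str]",
                       ) -> tuple[list[str], list[str]]:
    """Split a focal gene list into (kept, excluded-as-unassigned).

    Genes the orthology inference left unassigned in this dataset are
    treated as probable assembly/annotation errors and dropped, with an
    audit line giving counts and percentages.
    """
    unassigned = set(matrix.unassigned.get(dataset, ()))
    focal = list(dict.fromkeys(focal_genes))  # preserve order, dedupe
    excluded = [g for g in focal if g in unassigned]
    kept = [g for g in focal if g not in unassigned]
    n = len(focal)
    if n:
        logger.info(
            "%s: %d/%d (%.2f%%) focal genes assigned to orthogroups; %d (%.2f%%) "
            "unassigned and excluded", dataset, len(kept), n, 100 * len(kept) / n,
            len(excluded), 100 * len(excluded) / n)
    if kept == [] and n:
        logger.warning("%s: every focal gene was unassigned", dataset)
    return kept, excluded


def assignment_percentages(n_assigned: int, n_unassigned: int) -> tuple[float, float]:
    """Report arithmetic for the assigned/unassigned split, in percent."""
    total = n_assigned + n_unassigned
    if total == 0:
        raise ValueError("no genes")
    return 100.0 * n_assigned / total, 100.0 * n_unassigned / total


def category_proportions(matrix: OrthogroupMatrix, assignments: dict[str, str],
                         focal_orthogroups: "list[str] | set[str]",
                         ) -> CategoryReport:
    """Per-category counts/proportions for the whole matrix and a focal set.

    Proportions in each ring sum to 1 (within 1e-12). Focal orthogroups must
    exist in the matrix.
    """
    missing = [og for og in matrix.orthogroup_ids if og not in assignments]
    if missing:
        raise ValueError(f"assignments missing for {len(missing)} orthogroup(s)")
    focal = set(focal_orthogroups)
    unknown = focal - set(matrix.orthogroup_ids)
    if unknown:
        raise ValueError(f"focal orthogroup(s) not in matrix: {sorted(unknown)[:3]}")

    cats = sorted({assignments[og] for og in matrix.orthogroup_ids})
    t_counts = {c: 0 for c in cats}
    f_counts = {c: 0 for c in cats}
    for og in matrix.orthogroup_ids:
        t_counts[assignments[og]] += 1
        if og in focal:
            f_counts[assignments[og]] += 1
    n_t = len(matrix.orthogroup_ids)
    n_f = len(focal)
    t_prop = {c: t_counts[c] / n_t for c in cats} if n_t else {}
    f_prop = {c: f_counts[c] / n_f for c in cats} if n_f else {c: 0.0 for c in cats}
    return CategoryReport(
        categories=cats,
        transcriptome_counts=t_counts,
        transcriptome_proportions=t_prop,
        focal_counts=f_counts,
        focal_proportions=f_prop,
        n_transcriptome=n_t,
        n_focal=n_f,
    )


def restricted_proportion(report: CategoryReport, ring: str = "focal") -> float:
    """Summed proportion of the taxonomically restricted categories
    (everything outside the three conserved classes and 'other')."""
    props = (report.focal_proportions if ring == "focal"
             else report.transcriptome_proportions)
    return sum(p for c, p in props.items()
               if c not in CONSERVED_CATEGORIES and c != OTHER_CATEGORY)
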
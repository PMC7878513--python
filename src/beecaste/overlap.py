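"""Cross-species comparison of differentially expressed gene sets.

Species are compared by their normalized annotation terms (the per-gene
free-text protein descriptions), never by sequence: the observed overlap
between two species' DE term sets is scored against a random-sampling null
in which each species' DE set size is redrawn uniformly without replacement
from its own annotated-transcriptome term universe. Empirical p-values use
the (+1)/(reps+1) convention and so are never exactly zero.

Manual curation (removal of partially/redundantly matching terms, e.g.
"transposase") is applied to the reported shared-term list only; the
random-sampling statistic always uses the uncurated computational overlap.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .io_core import DeTable, logger

UNINFORMATIVE_MARKER = "uncharacterized protein"

#: Terms the original curation flagged as partial or redundant annotation
#: matches; applied as literal substring patterns to reported overlaps.
DEFAULT_CURATION_PATTERNS = (
    "transposase",
    "transporter",
    "cytochrome c oxidase subunit",
)

_WS = re.compile(r"\s+")


@dataclass
class TermSet:
    """A species' DE term set in one stratum, with its term universe."""

    species: str
    stratum: str  # all | nurse | forager
    terms: set[str]
    universe: set[str]

    def __post_init__(self) -> None:
        if "" in self.terms or "" in self.universe:
            raise ValueError("normalized term sets must not contain the empty string")
        if not self.terms <= self.universe:
            raise ValueError(
                f"{self.species}/{self.stratum}: terms not a subset of the universe "
                f"(e.g. {sorted(self.terms - self.universe)[:3]})"
            )


@dataclass
class OverlapResult:
    """Observed term-set overlap with its resampling null summary."""

    observed: int
    shared_terms: list[str]
    expected_mean: float
    expected_sd: float
    p_value: float
    reps: int
    seed: int
    #: tie-randomized empirical p: exactly uniform under the null even though
    #: the overlap statistic is integer-valued; used for calibration checks,
    #: never for reporting significance.
    p_value_randomized: float = float("nan")
    stratum: str = "all"
    curated_terms: list[str] = field(default_factory=list)
    removed_terms: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.p_value < 0.01


def normalize_terms(raw: "list[str] | set[str] | tuple[str, ...]") -> set[str]:
    """Normalize free-text annotations into the comparison space.

    Lowercases, collapses internal whitespace, deduplicates, and removes
    empty entries and anything containing "uncharacterized protein"
    (uninformative placeholder annotations).
    """
    out: set[str] = set()
    for term in raw:
        t = _WS.sub(" ", str(term).strip().lower())
        if not t or UNINFORMATIVE_MARKER in t:
            continue
        out.add(t)
    return out


def curate_terms(terms: "set[str] | list[str]",
                 patterns: "tuple[str, ...] | list[str]" = DEFAULT_CURATION_PATTERNS,
                 ) -> tuple[set[str], list[str]]:
    """Split a term set into (kept, removed) by literal substring patterns.

    Mirrors the manual curation of reported overlap lists; the removed list
    is sorted so the curation is reproducible and auditable.
    """
    pats = [_WS.sub(" ", p.strip().lower()) for p in patterns if p.strip()]
    removed = sorted(t for t in terms if any(p in t for p in pats))
    kept = set(terms) - set(removed)
    if removed:
        logger.info("curation removed %d term(s): %s", len(removed), "; ".join(removed))
    return kept, removed


def term_set_from_table(table: DeTable, universe_annotations: "list[str] | set[str]",
                        stratum: str = "all") -> TermSet:
    """Build a normalized TermSet for one stratum of a DE table.

    `universe_annotations` are the raw annotations of the species' full
    annotated transcriptome; normalization drops unannotated/placeholder
    entries from both sets.
    """
    if stratum == "all":
        recs = table.records
    elif stratum in ("nurse", "forager"):
        recs = [r for r in table.records if r.bias == stratum]
    else:
        raise ValueError(f"unknown stratum {stratum!r}")
    universe = normalize_terms(universe_annotations)
    terms = normalize_terms([r.annotation for r in recs])
    extra = terms - universe
    if extra:
        # tolerate a universe file missing some DE annotations: extend it
        logger.warning("%s/%s: %d DE term(s) absent from the supplied universe; "
                       "universe extended", table.species, stratum, len(extra))
        universe |= extra
    return TermSet(species=table.species, stratum=stratum, terms=terms, universe=universe)


def _sample_intersections(universe_a: np.ndarray, universe_b: np.ndarray,
                          n_a: int, n_b: int, reps: int,
                          rng: np.random.Generator, vocab_size: int) -> np.ndarray:
    """Null intersection sizes: draw n_a ids from universe_a and n_b from
    universe_b without replacement, reps times."""
    sizes = np.empty(reps, dtype=np.int64)
    mask = np.zeros(vocab_size, dtype=bool)
    for r in range(reps):
        a = universe_a[rng.choice(universe_a.size, n_a, replace=False)]
        b = universe_b[rng.choice(universe_b.size, n_b, replace=False)]
        mask[a] = True
        sizes[r] = int(mask[b].sum())
        mask[a] = False
    return sizes


def overlap_random_test(a: TermSet, b: TermSet, reps: int = 10_000, seed: int = 0,
                        universe_mode: str = "per-species") -> OverlapResult:
    """Random-sampling overlap test between two species' DE term sets.

    observed = |A.terms ∩ B.terms|. The null redraws |A.terms| terms from
    A's universe and |B.terms| from B's (``per-species``, the default), or
    both from the union universe (``shared``, for closed-form oracles), and
    records the intersection size. One-sided empirical p for an overlap at
    least as large as observed, with the (+1)/(reps+1) convention.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if universe_mode not in ("per-species", "shared"):
        raise ValueError(f"unknown universe_mode {universe_mode!r}")
    if not a.universe or not b.universe:
        raise ValueError("empty universe")
    if len(a.terms) > len(a.universe) or len(b.terms) > len(b.universe):
        raise ValueError("term set larger than its universe")

    shared = sorted(a.terms & b.terms)
    observed = len(shared)

    if universe_mode == "shared":
        ua = ub = a.universe | b.universe
    else:
        ua, ub = a.universe, b.universe
    # fixed iteration order: set order varies with string hash randomization
    vocab = {t: i for i, t in enumerate(sorted(ua | ub))}
    arr_a = np.fromiter((vocab[t] for t in sorted(ua)), dtype=np.int64, count=len(ua))
    arr_b = np.fromiter((vocab[t] for t in sorted(ub)), dtype=np.int64, count=len(ub))

    rng = np.random.default_rng(seed)
    if a.terms and b.terms:
        sizes = _sample_intersections(arr_a, arr_b, len(a.terms), len(b.terms),
                                      reps, rng, len(vocab))
    else:
        sizes = np.zeros(reps, dtype=np.int64)

    n_greater = int((sizes > observed).sum())
    n_tied = int((sizes == observed).sum())
    p = (n_greater + n_tied + 1) / (reps + 1)
    p_rand = (n_greater + rng.random() * (n_tied + 1)) / (reps + 1)
    return OverlapResult(
        observed=observed,
        shared_terms=shared,
        expected_mean=float(sizes.mean()),
        expected_sd=float(sizes.std(ddof=1)) if reps > 1 else 0.0,
        p_value=min(p, 1.0),
        p_value_randomized=p_rand,
        reps=reps,
        seed=seed,
    )


def stratified_overlap(table_a: DeTable, universe_a: "list[str] | set[str]",
                       table_b: DeTable, universe_b: "list[str] | set[str]",
                       reps: int = 10_000, seed: int = 0,
                       universe_mode: str = "per-species",
                       curation: "tuple[str, ...] | list[str]" = DEFAULT_CURATION_PATTERNS,
                       ) -> dict[str, OverlapResult]:
    """Run the overlap test for the all/nurse/forager strata of two species.

    Curation is applied to each stratum's reported shared-term list; the
    statistic itself is computed on the uncurated overlap.
    """
    out: dict[str, OverlapResult] = {}
    for i, stratum in enumerate(("all", "nurse", "forager")):
        ts_a = term_set_from_table(table_a, universe_a, stratum)
        ts_b = term_set_from_table(table_b, universe_b, stratum)
        if stratum != "all" and (not ts_a.terms or not ts_b.terms):
            logger.warning("stratum %s missing in one species; skipped", stratum)
            continue
        res = overlap_random_test(ts_a, ts_b, reps=reps, seed=seed + i,
                                  universe_mode=universe_mode)
        kept, removed = curate_terms(set(res.shared_terms), curation)
        res.stratum = stratum
        res.curated_terms = sorted(kept)
        res.removed_terms = removed
        out[stratum] = res
    return out


def overlap_report(results: dict[str, OverlapResult], alpha: float = 0.01) -> str:
    """TSV report mirroring the published overlap table layout."""
    lines = ["stratum\tobserved\texpected_mean\texpected_sd\tp_value\tsignificant\t"
             "curated_observed\treps\tseed"]
    for stratum, r in results.items():
        lines.append(
            f"{stratum}\t{r.observed}\t{r.expected_mean:.4f}\t{r.expected_sd:.4f}\t"
            f"{r.p_value:.6g}\t{str(r.p_value < alpha).lower()}\t"
            f"{len(r.curated_terms)}\t{r.reps}\t{r.seed}"
        )
    return "\n".join(lines) + "\n"
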
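"""Synthetic inputs with the statistical structure the analysis assumes.

Every generator is a pure function of (params, seed): identical seeds give
identical outputs, and each generator emits a truth table sufficient to
score the downstream estimator it feeds.

The methylome generator plants cytosine sites as unambiguous dinucleotide
tiles separated by A/T spacers (no cytosine on either strand), so the
realized both-strand context census is exactly the planted multinomial
draw. CG sites are planted as palindromic CG dinucleotides and therefore
come in pairs, as in real DNA; the global CG site count is rounded to even
(a one-site perturbation at most).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import CGmapRecord, DeRecord, DeTable, OrthogroupMatrix
from .txr import (DEFAULT_CLADES, DEFAULT_DATASETS, DEFAULT_RULES, CategoryRule)

# Realized CG fractions of available C sites in the two study transcriptomes;
# the bumblebee value is the generator default, the stingless-bee value is a
# ready-made preset.
CG_FRACTION_BOMBUS = 0.2314
CG_FRACTION_TETRAGONISCA = 0.1544


def _default_context_mix() -> dict[str, float]:
    # CG fixed to the bumblebee census; remaining mass split over CA/CC/CT
    # with CA and CT favored (AT-rich insect transcriptome).
    rest = 1.0 - CG_FRACTION_BOMBUS
    return {"CG": CG_FRACTION_BOMBUS, "CA": 0.40 * rest, "CC": 0.20 * rest,
            "CT": 0.40 * rest}


@dataclass
class MethylomeSimParams:
    """Conditions for the methylome generator.

    Methylation is sparse and CG-enriched, as in bee gene bodies: a site is
    methylated with a context-specific probability and, if methylated, its
    level is Beta(5,1)-distributed (high, reflecting the bimodality of
    gene-body mC); unmethylated sites report zero methylated reads. Coverage
    is negative binomial (overdispersed) so the 10x filter is consequential.
    Expression is log-normal, positively coupled to a transcript's CG
    methylation propensity and independent of CW, reproducing the reported
    sign pattern.
    """

    n_transcripts: int = 500
    mean_length: int = 300  # bp, transcript length scale
    context_mix: dict[str, float] = field(default_factory=_default_context_mix)
    p_meth: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.15, "CW": 0.02, "CC": 0.01})
    level_beta: tuple[float, float] = (5.0, 1.0)
    coverage_mean: float = 30.0
    coverage_dispersion: float = 0.3  # NB: var = mean + dispersion * mean^2
    expression_coupling_cg: float = 1.0  # slope on standardized CG propensity
    expression_noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        mix = np.array([self.context_mix[k] for k in ("CG", "CA", "CC", "CT")])
        if (mix < 0).any() or (mix > 1).any():
            raise ValueError("context_mix probabilities must be in [0,1]")
        if abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("context_mix must sum to 1")
        for k, v in self.p_meth.items():
            if not 0 <= v <= 1:
                raise ValueError(f"p_meth[{k}] outside [0,1]")
        if self.n_transcripts < 1 or self.mean_length < 12:
            raise ValueError("need n_transcripts >= 1 and mean_length >= 12")


@dataclass
class OverlapSimParams:
    """Paired DE tables over shared annotation-term universes with a planted
    overlap of exactly ``planted_overlap`` normalized terms."""

    universe_size_a: int = 1000
    universe_size_b: int = 1000
    shared_universe_size: int = 600
    de_size_a: int = 100
    de_size_b: int = 50
    planted_overlap: int = 15
    nurse_fraction_a: float = 0.4
    nurse_fraction_b: float = 0.6
    overlap_nurse_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        k = self.planted_overlap
        if k < 0 or k > min(self.de_size_a, self.de_size_b):
            raise ValueError("planted overlap exceeds a DE set size")
        if k > self.shared_universe_size:
            raise ValueError("planted overlap exceeds the shared universe")
        if self.shared_universe_size > min(self.universe_size_a, self.universe_size_b):
            raise ValueError("shared universe larger than a species universe")
        if self.de_size_a > self.universe_size_a or self.de_size_b > self.universe_size_b:
            raise ValueError("DE set larger than its universe")
        # room to keep non-planted picks disjoint
        if (self.de_size_b - k) > (self.universe_size_b - k - (self.de_size_a - k)):
            raise ValueError("universes too small to keep the planted overlap exact")


@dataclass
class OrthoSimParams:
    """Orthogroup presence matrix with planted category labels."""

    dataset_ids: tuple[str, ...] = DEFAULT_DATASETS
    category_counts: dict[str, int] = field(default_factory=lambda: {
        "apinae": 60,
        "corbiculates": 25,
        "social_corbiculates": 20,
        "bumblebees": 12,
        "stingless_bees_f": 10,
        "stingless_bees": 8,
        "bterrestris_g": 9,
        "species_specific_bterrestris": 7,
        "species_specific_tangustula": 6,
    })
    genes_per_cell: int = 2
    unassigned_counts: dict[str, int] = field(default_factory=lambda: {
        "B_terrestris_transcriptome": 30, "T_angustula_transcriptome": 40})
    seed: int = 0


@dataclass
class OntologySimParams:
    """Layered is_a ontology with one planted enriched term."""

    n_levels: int = 4
    branching: int = 3
    n_genes: int = 300
    study_size: int = 60
    planted_level: int = 3
    enrichment_odds: float = 8.0
    annotation_prob: float = 0.25  # per gene-leaf annotation density
    seed: int = 0

    def validate(self) -> None:
        if self.n_levels < 3:
            raise ValueError("need n_levels >= 3 so a third hierarchical level exists")
        if self.enrichment_odds <= 0:
            raise ValueError("enrichment odds must be positive")
        if self.study_size > self.n_genes:
            raise ValueError("study set larger than the gene universe")


# ================================================================ methylome

_SPACER = "TT"
_TILES = {"CG": "CG", "CA": "CA", "CT": "CT", "CC": "CCN"}
# defined C sites contributed per tile (CG tile is palindromic: 2 sites)
_TILE_SITES = {"CG": 2, "CA": 1, "CT": 1, "CC": 1}


def simulate_methylome(params: MethylomeSimParams,
                       ) -> tuple[list[tuple[str, str]], list[CGmapRecord], pd.DataFrame]:
    """Generate (FASTA records, CGmap records, per-transcript truth table).

    The FASTA census matches the planted context mix exactly (one global
    multinomial draw over all C sites); CGmap rows are consistent with the
    FASTA dinucleotides on both strands. The truth table carries, per
    transcript, site/methylation counts per context class, the true mean mC,
    and the simulated normalized expression with its planted CG coupling.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    # sites per transcript: proportional to length (1 site per ~6 bp of tile+spacer)
    lengths = np.maximum(rng.poisson(params.mean_length, params.n_transcripts), 24)
    sites_per_t = np.maximum(lengths // 6, 2)
    total_sites = int(sites_per_t.sum())

    mix = params.context_mix
    counts = rng.multinomial(total_sites, [mix["CG"], mix["CA"], mix["CC"], mix["CT"]])
    n_cg, n_ca, n_cc, n_ct = (int(c) for c in counts)
    if n_cg % 2:  # CG sites come in palindromic pairs
        n_cg += 1 if rng.random() < 0.5 and n_ca > 0 else -1
        n_ca = total_sites - n_cg - n_cc - n_ct

    # one global pool of tile labels; CG tiles carry two sites each
    tiles = (["CG"] * (n_cg // 2) + ["CA"] * n_ca + ["CC"] * n_cc + ["CT"] * n_ct)
    rng.shuffle(tiles)

    # per-transcript methylation propensity multipliers (independent for CG / CW-CC)
    prop_cg = rng.gamma(4.0, 0.25, params.n_transcripts)  # mean 1
    prop_cw = rng.gamma(4.0, 0.25, params.n_transcripts)

    fasta: list[tuple[str, str]] = []
    cgmap: list[CGmapRecord] = []
    truth_rows = []
    tile_cursor = 0
    a_lvl, b_lvl = params.level_beta

    for t in range(params.n_transcripts):
        sid = f"st{t + 1:05d}"
        want = int(sites_per_t[t])
        seq_parts = [_SPACER]
        pos = len(_SPACER)  # 0-based index of next append
        site_count = 0
        n_sites_cls = {"CG": 0, "CW": 0, "CC": 0}
        n_meth_cls = {"CG": 0, "CW": 0, "CC": 0}
        true_levels: list[float] = []
        pending: list[tuple[int, str, str, str]] = []  # position(1-based), nuc, dinuc, cls

        while site_count < want and tile_cursor < len(tiles):
            label = tiles[tile_cursor]
            if site_count + _TILE_SITES[label] > want and label == "CG":
                # look ahead for a single-site tile to finish the transcript
                swap = next((j for j in range(tile_cursor + 1, len(tiles))
                             if _TILE_SITES[tiles[j]] == 1), None)
                if swap is None:
                    break
                tiles[tile_cursor], tiles[swap] = tiles[swap], tiles[tile_cursor]
                label = tiles[tile_cursor]
            tile_cursor += 1
            tile = _TILES[label]
            if label == "CG":
                # plus-strand C at pos, minus-strand C at pos+1 (the G)
                pending.append((pos + 1, "C", "CG", "CG"))
                pending.append((pos + 2, "G", "CG", "CG"))
                site_count += 2
            elif label in ("CA", "CT"):
                pending.append((pos + 1, "C", label, "CW"))
                site_count += 1
            else:  # CC tile "CCN": first C defined (CC), second killed by N
                pending.append((pos + 1, "C", "CC", "CC"))
                site_count += 1
            seq_parts.append(tile)
            pos += len(tile)
            seq_parts.append(_SPACER)
            pos += len(_SPACER)

        seq = "".join(seq_parts)
        fasta.append((sid, seq))

        for position, nuc, dinuc, cls in pending:
            n_sites_cls[cls] += 1
            p_m = params.p_meth["CG"] * prop_cg[t] if cls == "CG" else (
                params.p_meth["CW"] * prop_cw[t] if cls == "CW"
                else params.p_meth["CC"] * prop_cw[t])
            p_m = min(p_m, 1.0)
            methylated = rng.random() < p_m
            true_level = float(rng.beta(a_lvl, b_lvl)) if methylated else 0.0
            # NB coverage: gamma-poisson with shape 1/dispersion
            shape = 1.0 / params.coverage_dispersion
            lam = rng.gamma(shape, params.coverage_mean / shape)
            coverage = max(int(rng.poisson(lam)), 1)  # site was observed at least once
            mc = int(rng.binomial(coverage, true_level)) if methylated else 0
            if methylated:
                n_meth_cls[cls] += 1
            true_levels.append(true_level)
            context3 = "CG" if dinuc == "CG" else "CHH"
            cgmap.append(CGmapRecord(
                seq_id=sid, nucleotide=nuc, position=position, context3=context3,
                dinucleotide=dinuc, level=round(mc / coverage, 2), mc_count=mc,
                coverage=coverage))

        truth_rows.append({
            "seq_id": sid,
            "n_sites_CG": n_sites_cls["CG"],
            "n_sites_CW": n_sites_cls["CW"],
            "n_sites_CC": n_sites_cls["CC"],
            "n_meth_CG": n_meth_cls["CG"],
            "n_meth_CW": n_meth_cls["CW"],
            "n_meth_CC": n_meth_cls["CC"],
            "true_mean_mC": 100.0 * float(np.mean(true_levels)) if true_levels else 0.0,
            "propensity_CG": float(prop_cg[t]),
            "propensity_CW": float(prop_cw[t]),
        })

    truth = pd.DataFrame(truth_rows).set_index("seq_id")
    # expression: log-normal, coupled to standardized CG propensity only
    z = (truth["propensity_CG"] - truth["propensity_CG"].mean()) / truth["propensity_CG"].std()
    log_expr = (params.expression_coupling_cg * z.to_numpy()
                + rng.normal(0, params.expression_noise_sd, params.n_transcripts))
    truth["norm_count"] = np.exp(3.0 + log_expr)
    return fasta, cgmap, truth


# ================================================================ DE pair

def simulate_de_pair(params: OverlapSimParams,
                     ) -> tuple[DeTable, DeTable, dict[str, list[str]], pd.DataFrame]:
    """Generate two annotated DE tables whose normalized-term overlap is
    exactly the planted k, plus both term universes and a truth table.

    Universes share ``shared_universe_size`` terms; the k planted terms get
    the same subcaste bias in both species so stratified overlaps are exact.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    n_shared = params.shared_universe_size
    shared_terms = [f"shared term {i:05d}" for i in range(n_shared)]
    only_a = [f"species a term {i:05d}"
              for i in range(params.universe_size_a - n_shared)]
    only_b = [f"species b term {i:05d}"
              for i in range(params.universe_size_b - n_shared)]
    universe_a = shared_terms + only_a
    universe_b = shared_terms + only_b

    k = params.planted_overlap
    planted = list(rng.choice(shared_terms, size=k, replace=False)) if k else []
    planted_set = set(planted)

    pool_a = [t for t in universe_a if t not in planted_set]
    extras_a = list(rng.choice(pool_a, size=params.de_size_a - k, replace=False))
    pool_b = [t for t in universe_b if t not in planted_set and t not in set(extras_a)]
    extras_b = list(rng.choice(pool_b, size=params.de_size_b - k, replace=False))

    n_nurse_planted = int(round(params.overlap_nurse_fraction * k))
    planted_bias = (["nurse"] * n_nurse_planted
                    + ["forager"] * (k - n_nurse_planted))

    def build(species: str, extras: list[str], nurse_frac: float, tag: str) -> DeTable:
        n_extra_nurse = int(round(nurse_frac * (len(extras) + k))) - n_nurse_planted
        n_extra_nurse = min(max(n_extra_nurse, 0), len(extras))
        bias = planted_bias + (["nurse"] * n_extra_nurse
                               + ["forager"] * (len(extras) - n_extra_nurse))
        terms = planted + extras
        records = []
        for i, (term, b) in enumerate(zip(terms, bias)):
            lfc = float(rng.uniform(0.5, 4.0))
            if b == "nurse":
                lfc = -lfc  # forager-positive orientation
            records.append(DeRecord(
                gene_id=f"{tag}_g{i + 1:05d}", log_fc=lfc,
                p_value=float(rng.uniform(1e-6, 1e-3)), bias=b, annotation=term))
        return DeTable(species=species, records=records)

    table_a = build("species_a", extras_a, params.nurse_fraction_a, "a")
    table_b = build("species_b", extras_b, params.nurse_fraction_b, "b")

    truth = pd.DataFrame({
        "term": planted,
        "bias": planted_bias,
    })
    universes = {"species_a": universe_a, "species_b": universe_b}
    return table_a, table_b, universes, truth


# ================================================================ orthogroups

def _pattern_for_rule(rule: CategoryRule, datasets: tuple[str, ...],
                      clades: dict[str, set[str]], rng: np.random.Generator,
                      ) -> dict[str, bool]:
    """A canonical presence pattern satisfying one shipped category rule."""
    name = rule.name
    present: set[str] = set()
    all_ds = set(datasets)
    if name == "apinae":
        present = all_ds
    elif name == "corbiculates":
        present = all_ds - clades["outgroup"]
        # randomly thin one clade to one member to exercise the any-of-each reading
        clade = clades[["orchid_bees", "bumblebees", "honeybees",
                        "stingless_bees"][rng.integers(4)]]
        keep = set(rng.choice(sorted(clade), size=1))
        present -= (clade - keep)
    elif name == "social_corbiculates":
        present = all_ds - clades["outgroup"] - clades["orchid_bees"]
    elif name == "bumblebees":
        present = {"B_impatiens", "B_terrestris_transcriptome"}
        if rng.random() < 0.5:
            present.add("B_terrestris_genome")
    elif name == "stingless_bees_f":
        present = {"F_varia", "M_quadrifasciata", "T_angustula_transcriptome"}
    elif name == "stingless_bees":
        present = {"M_quadrifasciata", "T_angustula_transcriptome"}
    elif name == "bterrestris_g":
        present = {"B_terrestris_transcriptome", "B_terrestris_genome"}
    elif name == "species_specific_bterrestris":
        present = {"B_terrestris_transcriptome"}
    elif name == "species_specific_tangustula":
        present = {"T_angustula_transcriptome"}
    else:
        raise ValueError(f"no generator recipe for category {name!r}")
    return {d: d in present for d in datasets}


def simulate_orthogroup_matrix(params: OrthoSimParams,
                               ) -> tuple[OrthogroupMatrix, dict[str, str]]:
    """Generate an orthogroup presence matrix with planted category labels.

    The shipped rule set classifies every generated row back to its planted
    label; requesting a category without a recipe raises. Per-dataset
    unassigned gene lists are attached for the exclusion audit.
    """
    rng = np.random.default_rng(params.seed)
    datasets = params.dataset_ids
    clades = DEFAULT_CLADES
    known = {r.name for r in DEFAULT_RULES}
    og_ids: list[str] = []
    genes: dict[str, dict[str, list[str]]] = {}
    labels: dict[str, str] = {}
    rows: list[list[int]] = []
    i = 0
    for category, n in params.category_counts.items():
        if category not in known:
            raise ValueError(f"rule set has no category {category!r}")
        rule = next(r for r in DEFAULT_RULES if r.name == category)
        for _ in range(n):
            i += 1
            og = f"OG{i:07d}"
            pattern = _pattern_for_rule(rule, datasets, clades, rng)
            og_ids.append(og)
            labels[og] = category
            per_ds: dict[str, list[str]] = {}
            row = []
            for d in datasets:
                if pattern[d]:
                    n_genes = int(rng.integers(1, params.genes_per_cell + 1))
                    per_ds[d] = [f"{d}|{og}|g{j}" for j in range(n_genes)]
                else:
                    per_ds[d] = []
                row.append(len(per_ds[d]))
            genes[og] = per_ds
            rows.append(row)
    counts = pd.DataFrame(rows, index=og_ids, columns=list(datasets), dtype=int)
    unassigned = {d: [f"{d}|unassigned|g{j}" for j in range(n)]
                  for d, n in params.unassigned_counts.items()}
    matrix = OrthogroupMatrix(orthogroup_ids=og_ids, dataset_ids=list(datasets),
                              counts=counts, genes=genes, unassigned=unassigned)
    return matrix, labels


# ================================================================ ontology

def simulate_ontology(params: OntologySimParams,
                      ) -> tuple["OntologyDag", dict[str, set[str]], set[str], dict]:
    """Generate a layered is_a tree, gene annotations, a study set with one
    planted enriched term, and the truth record.

    Genes are annotated to leaf terms; the study set is drawn without
    replacement with weight ``enrichment_odds`` on genes carrying the
    planted term (odds 1 = null draw).
    """
    from .io_core import OntologyDag  # local import to avoid cycle at module load

    params.validate()
    rng = np.random.default_rng(params.seed)

    terms: dict[str, tuple[str, str]] = {}
    is_a: dict[str, set[str]] = {}
    levels: list[list[str]] = []
    root = "T:0000001"
    terms[root] = ("biological_process", "biological_process")
    levels.append([root])
    counter = 1
    for lvl in range(2, params.n_levels + 1):
        layer = []
        for parent in levels[-1]:
            for _ in range(params.branching):
                counter += 1
                tid = f"T:{counter:07d}"
                terms[tid] = (f"process {counter}", "biological_process")
                is_a[tid] = {parent}
                layer.append(tid)
        levels.append(layer)
    dag = OntologyDag(terms=terms, is_a=is_a, root_ids={root})

    leaves = levels[-1]
    planted_term = levels[params.planted_level - 1][0]
    # leaves under the planted term
    def under(term: str, leaf: str) -> bool:
        return term == leaf or term in dag.ancestors(leaf)
    planted_leaves = [lf for lf in leaves if under(planted_term, lf)]
    other_leaves = [lf for lf in leaves if lf not in set(planted_leaves)]

    genes = [f"g{i:05d}" for i in range(params.n_genes)]
    annotations: dict[str, set[str]] = {}
    for g in genes:
        n_terms = 1 + rng.binomial(2, params.annotation_prob)
        annotations[g] = set(rng.choice(leaves, size=n_terms, replace=False))

    carries = np.array([bool(annotations[g] & set(planted_leaves)) for g in genes])
    weights = np.where(carries, params.enrichment_odds, 1.0)
    weights = weights / weights.sum()
    study = set(map(str, rng.choice(genes, size=params.study_size, replace=False,
                                    p=weights)))

    truth = {
        "planted_term": planted_term,
        "planted_level": params.planted_level,
        "n_carriers": int(carries.sum()),
        "n_study_carriers": sum(1 for g in study if annotations[g] & set(planted_leaves)),
        "leaves_under_planted": planted_leaves,
    }
    return dag, annotations, study, truth
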
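"""Context-resolved gene-body DNA methylation statistics.

Bisulfite calls are consumed in transcript space (reads mapped to
superTranscripts, not a genome), so every statistic here is per-transcript
or per-gene-set. Cytosine contexts are collapsed to the dinucleotide
classes used for bees: CG, CW (= CA or CT) and CC. The module covers the
10x coverage filter, the both-strand context census of a transcriptome, the
context composition of methylated cytosines, per-transcript mean mC, the
one-tailed z-test of a gene set's mean against the transcriptome, the
random-sampling CG-enrichment test, and Spearman coupling between
methylation and normalized expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import CGmapRecord, logger

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

CONTEXT_CLASSES = ("CG", "CW", "CC")


def context_class(dinucleotide: str) -> str:
    """Collapse a C-dinucleotide to its class: CG, CW (CA/CT) or CC."""
    if dinucleotide == "CG":
        return "CG"
    if dinucleotide in ("CA", "CT"):
        return "CW"
    if dinucleotide == "CC":
        return "CC"
    raise ValueError(f"not a cytosine dinucleotide: {dinucleotide!r}")


@dataclass
class TranscriptMethylation:
    """Per-transcript methylation summary over covered cytosine sites."""

    seq_id: str
    covered_sites: dict[str, int]  # per context class
    methylated_sites: dict[str, int]
    mean_mC: float  # unweighted mean of site levels, percent
    weighted_mC: float  # sum(mc)/sum(coverage), percent
    context_mean_levels: dict[str, float]  # per class, percent (NaN if no sites)

    @property
    def n_sites(self) -> int:
        return sum(self.covered_sites.values())


@dataclass
class SetTestResult:
    """One-tailed z-test of a gene subset's mean mC against the
    transcriptome-wide per-transcript distribution."""

    label: str
    subset_mean: float
    global_mean: float
    z: float
    p_value: float
    ci_low: float
    ci_high: float
    n_subset: int
    percent_difference: float
    tail: str


@dataclass
class CorrelationResult:
    context: str
    r_s: float
    p_value: float
    n: int


# ---------------------------------------------------------------- filtering

def filter_coverage(records: "list[CGmapRecord]", min_cov: int = 10) -> list[CGmapRecord]:
    """Drop sites with coverage below ``min_cov`` (default 10x)."""
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    kept = [r for r in records if r.coverage >= min_cov]
    dropped = len(records) - len(kept)
    if records:
        logger.info("coverage filter (<%dx): dropped %d/%d sites (%.1f%%)",
                    min_cov, dropped, len(records), 100 * dropped / len(records))
    return kept


# ---------------------------------------------------------------- census

def census_sequence(seq: str) -> dict[str, int]:
    """Count C sites per dinucleotide on both strands of one sequence.

    A plus-strand C at i has dinucleotide C + seq[i+1]; a plus-strand G at i
    is a minus-strand C whose following base is the complement of seq[i-1].
    Sites whose partner base is N/ambiguous or falls off the sequence end go
    to the "undefined" bucket.
    """
    counts = {"CA": 0, "CC": 0, "CG": 0, "CT": 0, "undefined": 0}
    n = len(seq)
    for i, base in enumerate(seq):
        if base == "C":
            nxt = seq[i + 1] if i + 1 < n else None
            if nxt in ("A", "C", "G", "T"):
                counts["C" + nxt] += 1
            else:
                counts["undefined"] += 1
        elif base == "G":
            prv = seq[i - 1] if i > 0 else None
            comp = COMPLEMENT.get(prv) if prv else None
            if comp:
                counts["C" + comp] += 1
            else:
                counts["undefined"] += 1
    return counts


def context_census(fasta: "list[tuple[str, str]]") -> dict[str, float]:
    """Proportion of defined C sites per dinucleotide class over a
    transcriptome (both strands). Returns NaN proportions when no C site
    has a defined context."""
    total = {"CA": 0, "CC": 0, "CG": 0, "CT": 0, "undefined": 0}
    for _, seq in fasta:
        for k, v in census_sequence(seq).items():
            total[k] += v
    defined = sum(total[k] for k in ("CA", "CC", "CG", "CT"))
    if defined == 0:
        logger.warning("context census: no C site with a defined context")
        return {"CG": float("nan"), "CW": float("nan"), "CC": float("nan"),
                "n_defined": 0, "n_undefined": total["undefined"]}
    return {
        "CG": total["CG"] / defined,
        "CW": (total["CA"] + total["CT"]) / defined,
        "CC": total["CC"] / defined,
        "n_defined": defined,
        "n_undefined": total["undefined"],
    }


# ---------------------------------------------------------------- calls

def call_methylated(record: CGmapRecord, rule: str = "any",
                    error_rate: float = 0.005, alpha: float = 0.01) -> bool:
    """Decide whether a (coverage-filtered) site is methylated.

    rule="any": at least one methylated read (the default reading of
    "methylated cytosines reported"). rule="binomial": one-sided binomial
    test of mc_count against the bisulfite non-conversion error rate.
    """
    if record.mc_count == 0:
        return False
    if rule == "any":
        return record.mc_count >= 1
    if rule == "binomial":
        p = stats.binom.sf(record.mc_count - 1, record.coverage, error_rate)
        return bool(p < alpha)
    raise ValueError(f"unknown call rule {rule!r}")


def methylated_records(records: "list[CGmapRecord]", rule: str = "any",
                       error_rate: float = 0.005, alpha: float = 0.01,
                       ) -> list[CGmapRecord]:
    return [r for r in records if call_methylated(r, rule, error_rate, alpha)]


def methylation_context_composition(records: "list[CGmapRecord]",
                                    rule: str = "any") -> dict[str, float]:
    """Percent of methylated cytosines per context class (CG/CW/CC).

    Sums to 100 when at least one methylated site exists; all-NaN with a
    warning otherwise. Input should already be coverage-filtered.
    """
    meth = methylated_records(records, rule)
    if not meth:
        logger.warning("context composition: zero methylated sites")
        return {"CG": float("nan"), "CW": float("nan"), "CC": float("nan"), "n_methylated": 0}
    counts = {"CG": 0, "CW": 0, "CC": 0}
    for r in meth:
        counts[context_class(r.dinucleotide)] += 1
    m = len(meth)
    return {k: 100.0 * v / m for k, v in counts.items()} | {"n_methylated": m}


# ---------------------------------------------------------------- per-transcript

def transcript_mC(records: "list[CGmapRecord]", rule: str = "any",
                  ) -> dict[str, TranscriptMethylation]:
    """Per-transcript methylation summaries from (filtered) CGmap records.

    mean_mC is the unweighted arithmetic mean of site levels (in percent);
    weighted_mC is total methylated reads over total coverage. Transcripts
    appear only if they have at least one covered site.
    """
    by_seq: dict[str, list[CGmapRecord]] = {}
    for r in records:
        by_seq.setdefault(r.seq_id, []).append(r)
    out: dict[str, TranscriptMethylation] = {}
    for sid, recs in by_seq.items():
        covered = {c: 0 for c in CONTEXT_CLASSES}
        methylated = {c: 0 for c in CONTEXT_CLASSES}
        levels_by_class: dict[str, list[float]] = {c: [] for c in CONTEXT_CLASSES}
        mc_total = 0
        cov_total = 0
        for r in recs:
            cls = context_class(r.dinucleotide)
            covered[cls] += 1
            lvl = r.mc_count / r.coverage if r.coverage else 0.0
            levels_by_class[cls].append(lvl)
            if call_methylated(r, rule):
                methylated[cls] += 1
            mc_total += r.mc_count
            cov_total += r.coverage
        all_levels = [lv for lvs in levels_by_class.values() for lv in lvs]
        out[sid] = TranscriptMethylation(
            seq_id=sid,
            covered_sites=covered,
            methylated_sites=methylated,
            mean_mC=100.0 * float(np.mean(all_levels)),
            weighted_mC=100.0 * mc_total / cov_total if cov_total else 0.0,
            context_mean_levels={
                c: (100.0 * float(np.mean(lvs)) if lvs else float("nan"))
                for c, lvs in levels_by_class.items()
            },
        )
    return out


def transcript_table(per_transcript: dict[str, TranscriptMethylation]) -> pd.DataFrame:
    rows = []
    for sid, t in per_transcript.items():
        rows.append({
            "seq_id": sid,
            "mean_mC": t.mean_mC,
            "weighted_mC": t.weighted_mC,
            "n_sites": t.n_sites,
            "covered_CG": t.covered_sites["CG"],
            "covered_CW": t.covered_sites["CW"],
            "covered_CC": t.covered_sites["CC"],
            "methylated_CG": t.methylated_sites["CG"],
            "methylated_CW": t.methylated_sites["CW"],
            "methylated_CC": t.methylated_sites["CC"],
            "mean_mC_CG": t.context_mean_levels["CG"],
            "mean_mC_CW": t.context_mean_levels["CW"],
            "mean_mC_CC": t.context_mean_levels["CC"],
        })
    return pd.DataFrame(rows).set_index("seq_id") if rows else pd.DataFrame()


# ---------------------------------------------------------------- set tests

def subset_mean_ztest(subset_values: "np.ndarray | list[float]",
                      global_values: "np.ndarray | list[float]",
                      tail: str = "auto", label: str = "subset") -> SetTestResult:
    """One-tailed z-test: is a gene set's mean mC different from the
    transcriptome-wide mean?

    The transcriptome-wide per-transcript distribution supplies the
    population mean and SD; z = (x̄_sub − μ)/(σ/√n). tail="greater"/"less"
    fixes the alternative; tail="auto" takes the tail on the side of the
    observed difference. The 95% CI is on the subset mean (population-σ
    based). Also reports the percent difference from the global mean.
    """
    sub = np.asarray(subset_values, dtype=float)
    glob = np.asarray(global_values, dtype=float)
    if sub.size < 2:
        raise ValueError("subset must contain at least 2 transcripts")
    mu = float(glob.mean())
    sigma = float(glob.std(ddof=0))
    if sigma == 0:
        raise ValueError("degenerate population: global SD is zero")
    se = sigma / np.sqrt(sub.size)
    xbar = float(sub.mean())
    z = (xbar - mu) / se
    if tail == "greater":
        p = float(stats.norm.sf(z))
    elif tail == "less":
        p = float(stats.norm.cdf(z))
    elif tail == "auto":
        p = float(stats.norm.sf(abs(z)))
        tail = "greater" if z >= 0 else "less"
    else:
        raise ValueError(f"unknown tail {tail!r}")
    half = 1.959963984540054 * se
    return SetTestResult(
        label=label,
        subset_mean=xbar,
        global_mean=mu,
        z=float(z),
        p_value=p,
        ci_low=xbar - half,
        ci_high=xbar + half,
        n_subset=int(sub.size),
        percent_difference=100.0 * (xbar - mu) / mu if mu != 0 else float("nan"),
        tail=tail,
    )


def cg_enrichment_test(records: "list[CGmapRecord]", census: dict[str, float],
                       reps: int = 10_000, seed: int = 0, rule: str = "any") -> dict:
    """Random-sampling test: is the CG share of methylated cytosines larger
    than expected from the availability of CG sites?

    Each draw assigns the observed number of methylated sites to contexts
    with the census probabilities and records the CG fraction; one-sided
    empirical p with the (+1)/(reps+1) convention.
    """
    meth = methylated_records(records, rule)
    m = len(meth)
    if m == 0:
        raise ValueError("no methylated sites")
    observed = sum(1 for r in meth if context_class(r.dinucleotide) == "CG") / m
    p_cg = census["CG"]
    if not 0 <= p_cg <= 1:
        raise ValueError("census CG proportion must be in [0,1]")
    rng = np.random.default_rng(seed)
    draws = rng.binomial(m, p_cg, size=reps) / m
    p = (int((draws >= observed).sum()) + 1) / (reps + 1)
    return {
        "observed_cg_fraction": observed,
        "expected_cg_fraction": p_cg,
        "p_value": min(p, 1.0),
        "n_methylated": m,
        "reps": reps,
        "seed": seed,
    }


# ---------------------------------------------------------------- coupling

def methylation_expression_correlation(per_transcript: dict[str, TranscriptMethylation],
                                       norm_counts: dict[str, float],
                                       subset: "set[str] | None" = None,
                                       ) -> dict[str, CorrelationResult]:
    """Spearman correlation between per-transcript context mC and normalized
    expression, separately for the CG and CW contexts.

    Pairs are matched by seq_id; NaN methylation values (no covered site in
    that context) and missing expression values are dropped listwise per
    context. Requires at least 3 pairs.
    """
    ids = [sid for sid in per_transcript if sid in norm_counts
           and (subset is None or sid in subset)]
    out: dict[str, CorrelationResult] = {}
    for ctx in ("CG", "CW"):
        xs, ys = [], []
        for sid in ids:
            m = per_transcript[sid].context_mean_levels[ctx]
            e = norm_counts[sid]
            if np.isnan(m) or e is None or np.isnan(e):
                continue
            xs.append(m)
            ys.append(e)
        if len(xs) < 3:
            raise ValueError(f"{ctx}: fewer than 3 complete pairs")
        rho, p = stats.spearmanr(xs, ys)
        out[ctx] = CorrelationResult(context=ctx, r_s=float(rho), p_value=float(p),
                                     n=len(xs))
    return out
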
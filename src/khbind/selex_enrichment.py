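"""SELEX read processing and exclusive k-mer enrichment statistics.

The selection contrasts a positively selected read pool against a control
pool.  After primer trimming, inserts from both pools are decomposed into
overlapping k-mers for a range of k; k-mers present in the positive pool but
absent from the control ("exclusive" k-mers) are ranked by their positive
count and assigned one-sided Fisher exact p-values on the 2x2 occurrence
table, adjusted across all k jointly by Benjamini-Hochberg.  The selected
species is single-stranded, so counting is strand-specific (no reverse
complement).

Significant k-mers are exported as FASTA for external motif discovery.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.special import gammaln
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ReadPool",
    "KmerCountTable",
    "EnrichedKmer",
    "read_fastq",
    "trim_primers",
    "count_kmers",
    "exclusive_kmers",
    "fisher_enrichment",
    "bh_adjust",
    "run_selex_pipeline",
]

_VALID = set("ACGTN")


@dataclass
class ReadPool:
    reads: list
    label: str = "positive"
    n_input: int = 0
    n_trimmed: int = 0

    def __post_init__(self):
        if self.n_trimmed > self.n_input:
            raise ValueError("n_trimmed cannot exceed n_input")


@dataclass
class KmerCountTable:
    k: int
    counts: dict
    total_occurrences: int
    n_reads: int


@dataclass
class EnrichedKmer:
    sequence: str
    k: int
    count_pos: int
    count_ctrl: int
    p_value: float
    q_value: float
    rank: int


def read_fastq(path) -> list[str]:
    """Read sequences from FASTQ (gzipped allowed, by .gz suffix)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [str(rec.seq).upper() for rec in SeqIO.parse(fh, "fastq")]


def _hamming_leq(a: str, b: str, max_mm: int) -> bool:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > max_mm:
                return False
    return True


def trim_primers(
    raw_reads: Iterable[str],
    forward_primer: str,
    reverse_primer: str,
    max_mismatches: int = 2,
    label: str = "positive",
) -> ReadPool:
    """Extract inserts from reads with the library geometry primer+insert+primer.

    Primers are matched anchored at the read ends, allowing up to
    ``max_mismatches`` substitutions each (no indels — the library geometry
    is fixed).  Reads missing either primer, too short, or containing
    characters outside ACGTN are discarded and logged.
    """
    if not forward_primer or not reverse_primer:
        raise ValueError("primers must be non-empty")
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    fwd, rev = forward_primer.upper(), reverse_primer.upper()
    lf, lr = len(fwd), len(rev)
    inserts = []
    n_input = n_bad_char = 0
    for read in raw_reads:
        n_input += 1
        read = read.upper()
        if set(read) - _VALID:
            n_bad_char += 1
            continue
        if len(read) < lf + lr:
            continue
        if _hamming_leq(read[:lf], fwd, max_mismatches) and _hamming_leq(read[-lr:], rev, max_mismatches):
            inserts.append(read[lf : len(read) - lr])
    if n_bad_char:
        logger.warning("%d read(s) discarded: invalid characters", n_bad_char)
    return ReadPool(reads=inserts, label=label, n_input=n_input, n_trimmed=len(inserts))


def count_kmers(pool: ReadPool, k: int) -> KmerCountTable:
    """Overlapping k-mer occurrence counts, strand-specific, N-windows excluded."""
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Counter = Counter()
    for read in pool.reads:
        for i in range(len(read) - k + 1):
            kmer = read[i : i + k]
            if "N" not in kmer:
                counts[kmer] += 1
    return KmerCountTable(
        k=k, counts=dict(counts), total_occurrences=sum(counts.values()), n_reads=len(pool.reads)
    )


def exclusive_kmers(pos: KmerCountTable, ctrl: KmerCountTable) -> list[str]:
    """k-mers of the positive pool absent from the control pool.

    Sorted by positive count descending, ties broken lexicographically.
    """
    if pos.k != ctrl.k:
        raise ValueError(f"k mismatch: {pos.k} vs {ctrl.k}")
    excl = set(pos.counts) - set(ctrl.counts)
    return sorted(excl, key=lambda s: (-pos.counts[s], s))


def fisher_pvalues(
    count_pos: np.ndarray, count_ctrl: np.ndarray, total_pos: int, total_ctrl: int
) -> np.ndarray:
    """Vectorized one-sided (enrichment-in-positive) Fisher exact p-values.

    For the table [[c_pos, T_pos−c_pos], [c_ctrl, T_ctrl−c_ctrl]] the
    one-sided Fisher p equals the hypergeometric upper tail
    P(X >= c_pos | N = T_pos+T_ctrl, K = c_pos+c_ctrl, n = T_pos), evaluated
    exactly (scipy's survival function; no continuity approximation).
    """
    if total_pos <= 0 or total_ctrl <= 0:
        raise ValueError("pool totals must be positive")
    c_pos = np.asarray(count_pos, dtype=np.int64)
    c_ctrl = np.asarray(count_ctrl, dtype=np.int64)
    N = total_pos + total_ctrl
    if np.all(c_ctrl == 0):
        # exclusive k-mers: c_pos is the upper end of the support, so the
        # tail is the single pmf term C(T_pos, c)/C(N, c), evaluated in log
        # space -- exact and much faster than the generic survival function
        logp = (
            gammaln(total_pos + 1)
            - gammaln(total_pos - c_pos + 1)
            - gammaln(N + 1)
            + gammaln(N - c_pos + 1)
        )
        return np.minimum(np.exp(logp), 1.0)
    return hypergeom.sf(c_pos - 1, N, c_pos + c_ctrl, total_pos)


def fisher_enrichment(kmer: str, pos: KmerCountTable, ctrl: KmerCountTable) -> float:
    """One-sided Fisher exact p for a single k-mer's occurrence table."""
    if len(kmer) != pos.k:
        raise ValueError("k-mer length does not match table k")
    c_pos = pos.counts.get(kmer, 0)
    c_ctrl = ctrl.counts.get(kmer, 0)
    return float(
        fisher_pvalues(np.array([c_pos]), np.array([c_ctrl]), pos.total_occurrences, ctrl.total_occurrences)[0]
    )


def bh_adjust(p_values: Sequence[float], fdr: float = 0.05):
    """Benjamini-Hochberg step-up adjustment.

    Returns (q_values, significant) aligned with the input order; significant
    iff q <= fdr.  Monotone enforcement is part of the step-up procedure.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return q, reject


def run_selex_pipeline(
    pos_fastq,
    ctrl_fastq,
    forward_primer: str,
    reverse_primer: str,
    k_min: int = 5,
    k_max: int = 20,
    fdr: float = 0.05,
    max_mismatches: int = 2,
    mode: str = "occurrence",
    bh_pooling: str = "joint",
    out_dir=None,
) -> pd.DataFrame:
    """Full SELEX enrichment analysis from two FASTQ pools.

    Trims primers from both pools, counts k-mers for every k in
    [k_min, k_max], forms exclusive k-mers, tests them with the one-sided
    Fisher exact test, adjusts across all k jointly (``bh_pooling="joint"``,
    default) or per k (``"per_k"``), and ranks by positive count (ties: p
    ascending, then lexicographic).

    mode="occurrence" counts k-mer occurrences with pool totals = total
    occurrences; mode="presence" counts reads containing the k-mer with pool
    totals = read counts.

    Returns the ranked table; when ``out_dir`` is given also writes
    ``enriched_kmers.tsv`` and ``significant_kmers.fasta``.
    """
    if mode not in ("occurrence", "presence"):
        raise ValueError(f"unknown mode {mode!r}")
    pools = {}
    for label, path in (("positive", pos_fastq), ("control", ctrl_fastq)):
        pool = trim_primers(read_fastq(path), forward_primer, reverse_primer, max_mismatches, label)
        if pool.n_trimmed == 0:
            raise RuntimeError(
                f"no reads survive primer trimming in the {label} pool "
                f"({pool.n_input} input reads; check primers and max_mismatches)"
            )
        pools[label] = pool

    rows = []
    for k in range(k_min, k_max + 1):
        if mode == "presence":
            pos_t = _presence_table(pools["positive"], k)
            ctrl_t = _presence_table(pools["control"], k)
        else:
            pos_t = count_kmers(pools["positive"], k)
            ctrl_t = count_kmers(pools["control"], k)
        if pos_t.total_occurrences == 0 or ctrl_t.total_occurrences == 0:
            continue
        excl = exclusive_kmers(pos_t, ctrl_t)
        if not excl:
            continue
        c_pos = np.array([pos_t.counts[s] for s in excl], dtype=np.int64)
        p = fisher_pvalues(c_pos, np.zeros_like(c_pos), pos_t.total_occurrences, ctrl_t.total_occurrences)
        rows.append(
            pd.DataFrame(
                {"kmer": excl, "k": k, "count_pos": c_pos, "count_ctrl": 0, "p": p}
            )
        )

    if not rows:
        df = pd.DataFrame(columns=["kmer", "k", "count_pos", "count_ctrl", "p", "q", "significant", "rank"])
    else:
        df = pd.concat(rows, ignore_index=True)
        if bh_pooling == "joint":
            q, sig = bh_adjust(df["p"].to_numpy(), fdr)
            df["q"], df["significant"] = q, sig
        elif bh_pooling == "per_k":
            df["q"], df["significant"] = np.nan, False
            for k, idx in df.groupby("k").groups.items():
                q, sig = bh_adjust(df.loc[idx, "p"].to_numpy(), fdr)
                df.loc[idx, "q"], df.loc[idx, "significant"] = q, sig
        else:
            raise ValueError(f"unknown bh_pooling {bh_pooling!r}")
        df = df.sort_values(
            ["count_pos", "p", "kmer"], ascending=[False, True, True], kind="mergesort"
        ).reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / "enriched_kmers.tsv", sep="\t", index=False)
        with open(out_dir / "significant_kmers.fasta", "w") as fh:
            for row in df[df["significant"]].itertuples():
                fh.write(f">kmer_rank{row.rank}_k{row.k}_n{row.count_pos}\n{row.kmer}\n")
    return df


def _presence_table(pool: ReadPool, k: int) -> KmerCountTable:
    """Read-level presence counts: each read contributes each k-mer at most once."""
    counts: Counter = Counter()
    for read in pool.reads:
        seen = {read[i : i + k] for i in range(len(read) - k + 1)}
        counts.update(s for s in seen if "N" not in s)
    return KmerCountTable(k=k, counts=dict(counts), total_occurrences=len(pool.reads), n_reads=len(pool.reads))
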
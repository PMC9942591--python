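"""Homolog filtering, redundancy clustering and representative selection.

Rate estimation needs a large, diverse, non-redundant set of homologues.
This module takes a hit table (as produced by a BLAST/HMMER-style search,
parsed from files — searches are never executed here), filters by identity
and coverage bounds, removes redundancy by greedy incremental clustering at
an identity threshold, and selects a target number of representatives
(150 by default) spread evenly along the E-value gradient.

Determinism: hits are canonically sorted by (E-value, subject id) before
clustering, so the same hit multiset always yields the same output — greedy
clustering is order-sensitive, and fixing the order fixes the result.
"""

from __future__ import annotations

import csv
import warnings

import numpy as np
from dataclasses import dataclass, field
from pathlib import Path

from Bio import Align

from .errors import MissingSequenceError, ParseError, TooFewHomologuesError


@dataclass(frozen=True)
class Hit:
    """One homolog search hit with its unaligned sequence."""

    subject_id: str
    e_value: float
    identity_to_query: float
    coverage_of_query: float
    sequence: str

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("e_value must be non-negative")
        if not (0.0 <= self.identity_to_query <= 1.0):
            raise ValueError("identity must be a fraction in [0, 1]")
        if not (0.0 <= self.coverage_of_query <= 1.0):
            raise ValueError("coverage must be a fraction in [0, 1]")
        if not self.sequence:
            raise MissingSequenceError(
                f"hit {self.subject_id!r} has no sequence; id-only hit tables "
                "are not supported (no database fetching)"
            )


@dataclass(frozen=True)
class SelectionConfig:
    """Similarity bounds, redundancy threshold and count policies."""

    min_identity: float = 0.35
    max_identity: float = 0.95
    min_coverage: float = 0.60
    redundancy_identity: float = 0.95
    n_representatives: int = 150
    min_homologues: int = 5     # hard floor, including the query
    warn_below: int = 50        # below this, analysis is not recommended
    warn_above: int = 300       # above this, computation becomes heavy

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_identity < self.max_identity <= 1.0):
            raise ValueError("need 0 <= min_identity < max_identity <= 1")
        if self.n_representatives < self.min_homologues:
            raise ValueError("n_representatives must be >= min_homologues")


@dataclass
class Cluster:
    representative: Hit
    members: list[Hit] = field(default_factory=list)


def sort_hits(hits: list[Hit]) -> list[Hit]:
    """Canonical order: ascending E-value, ties by subject id."""
    return sorted(hits, key=lambda h: (h.e_value, h.subject_id))


def filter_hits(
    hits: list[Hit], cfg: SelectionConfig, query_id: str | None = None
) -> list[Hit]:
    """Apply identity and coverage bounds; the query itself is exempt."""
    out = []
    for h in hits:
        if query_id is not None and h.subject_id == query_id:
            out.append(h)
            continue
        if not (cfg.min_identity <= h.identity_to_query <= cfg.max_identity):
            continue
        if h.coverage_of_query < cfg.min_coverage:
            continue
        out.append(h)
    return out


_cluster_aligner: Align.PairwiseAligner | None = None


def _get_cluster_aligner() -> Align.PairwiseAligner:
    global _cluster_aligner
    if _cluster_aligner is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = 1.0
        a.mismatch_score = 0.0
        a.open_gap_score = -1.0
        a.extend_gap_score = -1.0
        _cluster_aligner = a
    return _cluster_aligner


def pairwise_identity(a: str, b: str) -> float:
    """Identity of two unaligned sequences: matches in a global alignment
    (match +1 / mismatch 0 / gap -1) divided by the shorter length."""
    if not a or not b:
        return 0.0
    if a == b:
        return 1.0
    aln = _get_cluster_aligner().align(a, b)[0]
    matches = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for x, y in zip(a[a0:a1], b[b0:b1]):
            if x == y:
                matches += 1
    return matches / min(len(a), len(b))


def _char_counts(seq: str):
    arr = np.frombuffer(seq.encode("ascii", "replace"), dtype=np.uint8)
    return np.bincount(arr, minlength=128)


def cluster_redundant(hits_sorted: list[Hit], redundancy_identity: float) -> list[Cluster]:
    """Greedy incremental clustering in the given (canonical) order.

    Each hit joins the first existing cluster whose representative it
    matches at >= the threshold; otherwise it founds a new cluster. The
    representative of a cluster is its founder, which by the sort order has
    the smallest E-value in the cluster.

    A composition screen (shared character multiset is an upper bound on
    alignment matches) skips pairs that cannot reach the threshold, in the
    spirit of CD-HIT's short-word filters; it never changes the result.
    """
    clusters: list[Cluster] = []
    rep_counts: list = []
    for hit in hits_sorted:
        counts = _char_counts(hit.sequence)
        n = len(hit.sequence)
        for cl, rc in zip(clusters, rep_counts):
            shorter = min(n, len(cl.representative.sequence))
            if float(np.minimum(counts, rc).sum()) < redundancy_identity * shorter:
                continue  # identity cannot reach the threshold
            if pairwise_identity(hit.sequence, cl.representative.sequence) >= redundancy_identity:
                cl.members.append(hit)
                break
        else:
            clusters.append(Cluster(representative=hit, members=[hit]))
            rep_counts.append(counts)
    return clusters


def select_representatives(clusters: list[Cluster], query: Hit, n: int) -> list[Hit]:
    """At most ``n`` cluster representatives, evenly strided along the
    E-value-ordered cluster list so the full similarity gradient is kept;
    the query is always included."""
    reps = [cl.representative for cl in clusters]
    m = len(reps)
    if m <= n:
        selected = list(reps)
    else:
        indices = [i * m // n for i in range(n)]
        selected = [reps[i] for i in indices]
        if not any(h.subject_id == query.subject_id for h in selected):
            # cluster index holding the query (as representative or member)
            qi = next(
                (
                    k
                    for k, cl in enumerate(clusters)
                    if any(mb.subject_id == query.subject_id for mb in cl.members)
                ),
                0,
            )
            slot = min(range(len(indices)), key=lambda s: abs(indices[s] - qi))
            selected[slot] = query
    if not any(h.subject_id == query.subject_id for h in selected):
        selected[0] = query
    return selected


def enforce_counts(selected: list[Hit], cfg: SelectionConfig) -> list[Hit]:
    """Hard minimum and advisory warnings on the homolog count."""
    count = len(selected)
    if count < cfg.min_homologues:
        raise TooFewHomologuesError(
            f"{count} sequences (including the query); minimum is "
            f"{cfg.min_homologues}"
        )
    if count < cfg.warn_below:
        warnings.warn(
            f"only {count} homologues (including the query); analyses with "
            f"fewer than {cfg.warn_below} are not recommended",
            UserWarning,
            stacklevel=2,
        )
    elif count > cfg.warn_above:
        warnings.warn(
            f"{count} homologues; more than {cfg.warn_above} makes the rate "
            "computation very slow and is not recommended",
            UserWarning,
            stacklevel=2,
        )
    return selected


def select_homologues(
    hits: list[Hit], query: Hit, cfg: SelectionConfig | None = None
) -> list[Hit]:
    """Full selection pipeline: sort, filter, de-redundify, stride-sample,
    count-check. The query survives every stage."""
    cfg = cfg or SelectionConfig()
    pool = list(hits)
    if not any(h.subject_id == query.subject_id for h in pool):
        pool.append(query)
    ordered = sort_hits(filter_hits(pool, cfg, query_id=query.subject_id))
    clusters = cluster_redundant(ordered, cfg.redundancy_identity)
    selected = select_representatives(clusters, query, cfg.n_representatives)
    return enforce_counts(selected, cfg)


# ---------------------------------------------------------------------------
# hit-table readers


def _fraction(value: float) -> float:
    """Identity/coverage given as percent in files is divided by 100."""
    return value / 100.0 if value > 1.0 else value


def read_hits_blast_tabular(
    path: str | Path, sequences: dict[str, str], query_length: int
) -> list[Hit]:
    """BLAST outfmt-6-like TSV: qseqid sseqid pident length mismatch gapopen
    qstart qend sstart send evalue bitscore. Coverage is the aligned query
    span divided by the query length."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 11:
                raise ParseError(f"{path}:{lineno}: expected >= 11 tab-separated columns")
            sseqid = parts[1]
            seq = sequences.get(sseqid)
            if seq is None:
                raise MissingSequenceError(
                    f"{path}:{lineno}: no sequence provided for hit {sseqid!r}"
                )
            try:
                pident = float(parts[2])
                qstart, qend = int(parts[6]), int(parts[7])
                evalue = float(parts[10])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            coverage = (abs(qend - qstart) + 1) / query_length
            hits.append(
                Hit(
                    subject_id=sseqid,
                    e_value=evalue,
                    identity_to_query=_fraction(pident),
                    coverage_of_query=min(coverage, 1.0),
                    sequence=seq,
                )
            )
    return hits


def read_hits_tsv(path: str | Path, sequences: dict[str, str]) -> list[Hit]:
    """Generic TSV with header: subject_id, e_value, identity, coverage."""
    hits = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"subject_id", "e_value", "identity", "coverage"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ParseError(
                f"{path}: header must contain columns {sorted(required)}"
            )
        for row in reader:
            sid = row["subject_id"]
            seq = sequences.get(sid)
            if seq is None:
                raise MissingSequenceError(f"{path}: no sequence for hit {sid!r}")
            hits.append(
                Hit(
                    subject_id=sid,
                    e_value=float(row["e_value"]),
                    identity_to_query=_fraction(float(row["identity"])),
                    coverage_of_query=_fraction(float(row["coverage"])),
                    sequence=seq,
                )
            )
    return hits
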
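"""Cross-species conserved miRNA curation.

Three nested feature sets are produced from a differentially expressed (DE)
miRNA list and the mature sequence sets of two species:

* ``sc`` (sequentially conserved): DE features whose best global alignment
  against the second species' mature set reaches a minimum percent identity.
* ``fs`` (functionally similar): features re-assigned to their best match in
  the second species' reference, re-quantified under those identifiers and
  re-screened through the prefilter / TMM / factorial-ANOVA pipeline.
* ``cnvd`` (conserved): sc features whose homologue is in fs.

Alignments are exact global dynamic programming with affine gaps; every
query is scored against every reference sequence (short mature sequences
make the exhaustive scan cheap, so no heuristic pre-screen is used).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align, SeqIO

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignmentParams:
    """Nucleotide scoring: match/mismatch with affine gap penalties.

    Gap penalties are positive magnitudes (opening a gap costs
    ``-gap_open``; each additional gapped position costs ``-gap_extend``).
    """

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 0.1
    scoring_mode: str = "absolute"  # or "percent"

    def validate(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")
        if self.scoring_mode not in ("absolute", "percent"):
            raise ValueError("scoring_mode must be 'absolute' or 'percent'")


@dataclass(frozen=True)
class AlignmentResult:
    query: str
    target: str
    score: float
    pct_identity: float
    aligned_length: int


def _as_rna(seq: str) -> str:
    seq = seq.upper().replace("T", "U")
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"non-RNA characters in sequence: {sorted(bad)}")
    return seq


def _aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def align_pair(
    seq_a: str,
    seq_b: str,
    params: AlignmentParams | None = None,
    query: str = "query",
    target: str = "target",
) -> AlignmentResult:
    """Optimal global alignment of two RNA sequences with affine gaps.

    Percent identity is matches over alignment columns (gap columns count)
    times 100, measured on one optimal alignment; the score is the dynamic
    programming optimum. In ``percent`` scoring mode the reported score is
    rescaled by the maximal self-alignment score of the two sequences.
    """
    params = params or AlignmentParams()
    params.validate()
    a, b = _as_rna(seq_a), _as_rna(seq_b)
    aligner = _aligner(params)
    # first optimal alignment; co-optimal paths share the score, identity is
    # reported for this deterministic representative
    alignment = next(iter(aligner.align(a, b)))
    identities = alignment.counts().identities
    length = alignment.length
    score = float(alignment.score)
    if params.scoring_mode == "percent":
        best_self = max(len(a), len(b)) * params.match
        score = 100.0 * score / best_self if best_self else 0.0
    return AlignmentResult(query, target, score, 100.0 * identities / length, length)


def top_match(
    query_id: str,
    query_seq: str,
    reference: dict[str, str],
    params: AlignmentParams | None = None,
    tol: float = 1e-9,
) -> list[AlignmentResult]:
    """All reference sequences achieving the maximal alignment score.

    Ties are retained and ordered by target identifier.
    """
    if not reference:
        raise ValueError("reference set is empty")
    results = [
        align_pair(query_seq, seq, params, query=query_id, target=tid)
        for tid, seq in sorted(reference.items())
    ]
    best = max(r.score for r in results)
    return [r for r in results if r.score >= best - tol]


def read_fasta(path) -> dict[str, str]:
    """Mature sequences keyed by record id; T mapped to U, uppercase."""
    return {rec.id: _as_rna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


@dataclass
class ConservedSets:
    """The sc / fs / cnvd sets plus the query -> best-target homologue map."""

    sc: set[str]
    fs: set[str]
    cnvd: set[str]
    homologue_map: dict[str, list[AlignmentResult]] = field(default_factory=dict)

    def venn_counts(self) -> dict[str, int]:
        return {"sc": len(self.sc), "fs": len(self.fs), "cnvd": len(self.cnvd)}


def curate_sc(
    de_features,
    fasta_a: dict[str, str],
    fasta_b: dict[str, str],
    params: AlignmentParams | None = None,
    min_identity: float = 90.0,
) -> tuple[set[str], dict[str, list[AlignmentResult]]]:
    """Sequentially conserved DE features and their homologue map.

    A DE feature is sc if its top-scoring match in ``fasta_b`` reaches
    ``min_identity`` percent identity. Features missing from ``fasta_a`` are
    excluded with a log message.
    """
    sc: set[str] = set()
    homologues: dict[str, list[AlignmentResult]] = {}
    for feat in sorted(de_features):
        seq = fasta_a.get(feat)
        if seq is None:
            log.warning("DE feature %s missing from species-A FASTA; excluded", feat)
            continue
        matches = top_match(feat, seq, fasta_b, params)
        homologues[feat] = matches
        if any(m.pct_identity >= min_identity for m in matches):
            sc.add(feat)
    return sc, homologues


def reassign_to_reference(
    counts: pd.DataFrame,
    fasta_a: dict[str, str],
    reference: dict[str, str],
    params: AlignmentParams | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Aggregate counts of measured features onto their best reference match.

    Each measured feature with a sequence in ``fasta_a`` is assigned to its
    top-scoring reference identifier (first by identifier on ties) and
    counts sharing a reference identifier are summed.
    """
    mapping: dict[str, str] = {}
    for feat in counts.index:
        seq = fasta_a.get(feat)
        if seq is None:
            log.warning("feature %s has no sequence; dropped from re-assignment", feat)
            continue
        mapping[feat] = top_match(feat, seq, reference, params)[0].target
    if not mapping:
        return pd.DataFrame(columns=counts.columns), {}
    sub = counts.loc[list(mapping)]
    regrouped = sub.groupby(pd.Series(mapping), sort=True).sum()
    regrouped.index.name = counts.index.name
    return regrouped, mapping


def curate_fs(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    reference: dict[str, str],
    fasta_a: dict[str, str],
    params: AlignmentParams | None = None,
    alpha: float = 0.05,
    min_nonzero_frac: float = 0.40,
) -> tuple[set[str], dict[str, str]]:
    """Functionally similar features under the second species' identifiers.

    Re-assigns measured features to the reference, then re-runs the
    quantification screen (prefilter, TMM, log2 CPM, factorial ANOVA) on the
    aggregated matrix and returns the alpha-significant union.
    """
    from .anova import fit_four_way_anova
    from .normalize import cpm, normalized_log2_cpm, prefilter_features, tmm_factors

    regrouped, mapping = reassign_to_reference(counts, fasta_a, reference, params)
    if regrouped.empty:
        log.warning("no feature maps to the reference; fs set empty")
        return set(), mapping
    filtered = prefilter_features(regrouped, min_nonzero_frac)
    if filtered.empty:
        return set(), mapping
    factors = tmm_factors(filtered)
    expr = normalized_log2_cpm(cpm(filtered, factors))
    results = fit_four_way_anova(expr, meta, alpha=alpha)
    return set(results.de_union(alpha).union), mapping


def intersect_sets(
    sc: set[str],
    fs: set[str],
    homologue_map: dict[str, list[AlignmentResult]],
) -> ConservedSets:
    """cnvd = sc features whose mapped reference identifier is in fs."""
    cnvd = set()
    for feat in sc:
        matches = homologue_map.get(feat)
        if not matches:
            log.warning("sc feature %s has no homologue mapping; non-overlapping", feat)
            continue
        if any(m.target in fs for m in matches):
            cnvd.add(feat)
    return ConservedSets(set(sc), set(fs), cnvd, homologue_map)
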
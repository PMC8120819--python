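"""Cross-species best hits, reciprocal-best-hit orthologs, and expression screens.

Orthology between the two species is defined operationally: every protein of
one species is globally aligned against every protein of the other, the best
hit per query is kept, and a pair is called orthologous when the two proteins
are each other's best hit in both directions (RBH). Genes belonging to an RBH
pair are "common" genes; all others are "unique". Orthologs whose TPM values
differ by a large factor are flagged by the expression-divergence screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .seq import PairwiseAlignment, ProteinRecord, ScoringScheme, global_align, percent_identity


@dataclass(frozen=True)
class HitRecord:
    """Best-hit edge from a query protein to its top-scoring subject."""

    query_id: str
    subject_id: str
    identity: float  # percent, 0..100
    score: float
    n_columns: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError(f"identity must lie in [0,100], got {self.identity}")


@dataclass(frozen=True)
class OrthologPair:
    """A reciprocal best hit: idA (species A) <-> idB (species B)."""

    idA: str
    idB: str
    identity: float
    score: float


@dataclass(frozen=True)
class DivergenceFlag:
    """Expression-divergence call for one ortholog pair."""

    idA: str
    idB: str
    tpmA: float
    tpmB: float
    ratio: float
    flagged: bool


def best_hits(
    setA: Sequence[ProteinRecord],
    setB: Sequence[ProteinRecord],
    scheme: ScoringScheme | None = None,
    min_identity: float = 40.0,
) -> list[HitRecord]:
    """Best subject in ``setB`` for every query in ``setA``.

    For each query the subject with the highest alignment score wins; exact
    score ties are broken by identity, then by lexicographic subject id, so
    the result is deterministic. Hits with identity below ``min_identity``
    (percent) are dropped.
    """
    if not setA or not setB:
        raise ValueError("best_hits requires non-empty sequence sets")
    if not (0.0 <= min_identity <= 100.0):
        raise ValueError("min_identity must lie in [0,100]")
    idsA = {r.id for r in setA}
    idsB = {r.id for r in setB}
    shared = idsA & idsB
    if shared:
        raise ValueError(f"ids present in both species sets: {sorted(shared)[:5]}")
    scheme = scheme or ScoringScheme()
    hits: list[HitRecord] = []
    for query in setA:
        best: tuple[float, float, str] | None = None
        best_aln: PairwiseAlignment | None = None
        for subject in setB:
            aln = global_align(query, subject, scheme)
            ident = percent_identity(aln)
            # maximize (score, identity), minimize subject id on exact ties
            key = (aln.score, ident, subject.id)
            if best is None or (key[0], key[1]) > (best[0], best[1]) or (
                (key[0], key[1]) == (best[0], best[1]) and key[2] < best[2]
            ):
                best = key
                best_aln = aln
        assert best_aln is not None
        ident = percent_identity(best_aln)
        if ident >= min_identity:
            hits.append(
                HitRecord(
                    query_id=best_aln.query_id,
                    subject_id=best_aln.subject_id,
                    identity=ident,
                    score=best_aln.score,
                    n_columns=best_aln.n_columns,
                )
            )
    return hits


def reciprocal_best_hits(
    hitsAB: Sequence[HitRecord], hitsBA: Sequence[HitRecord]
) -> list[OrthologPair]:
    """Pairs (a, b) where b is a's best hit and a is b's best hit.

    Output is sorted by the species-A id. Empty inputs give an empty list.
    """
    forward = {h.query_id: h for h in hitsAB}
    backward = {h.query_id: h.subject_id for h in hitsBA}
    pairs = [
        OrthologPair(idA=a, idB=h.subject_id, identity=h.identity, score=h.score)
        for a, h in forward.items()
        if backward.get(h.subject_id) == a
    ]
    return sorted(pairs, key=lambda p: p.idA)


def classify_genes(
    setA: Sequence[ProteinRecord],
    setB: Sequence[ProteinRecord],
    pairs: Sequence[OrthologPair],
) -> pd.DataFrame:
    """Label every gene 'common' (member of an RBH pair) or 'unique'.

    Returns a DataFrame with columns (id, species, label). By construction the
    per-species common counts both equal the number of pairs.
    """
    idsA = {r.id for r in setA}
    idsB = {r.id for r in setB}
    common_a = {p.idA for p in pairs}
    common_b = {p.idB for p in pairs}
    unknown = (common_a - idsA) | (common_b - idsB)
    if unknown:
        raise ValueError(f"ortholog pairs reference unknown ids: {sorted(unknown)[:5]}")
    rows = [
        {"id": r.id, "species": "A", "label": "common" if r.id in common_a else "unique"}
        for r in setA
    ] + [
        {"id": r.id, "species": "B", "label": "common" if r.id in common_b else "unique"}
        for r in setB
    ]
    return pd.DataFrame(rows, columns=["id", "species", "label"])


def classification_summary(classified: pd.DataFrame) -> pd.DataFrame:
    """Per-species common/unique counts and fractions."""
    out = []
    for species, grp in classified.groupby("species"):
        n = len(grp)
        n_common = int((grp["label"] == "common").sum())
        out.append(
            {
                "species": species,
                "n_genes": n,
                "common": n_common,
                "unique": n - n_common,
                "common_fraction": n_common / n if n else 0.0,
            }
        )
    return pd.DataFrame(out)


def read_expression_table(path: str | Path) -> dict[str, float]:
    """Read a 2-column TSV (transcript_id, TPM) with a header row."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"expression table {path} must have two columns")
    ids = df.iloc[:, 0].astype(str)
    tpm = df.iloc[:, 1].astype(float)
    if (tpm < 0).any():
        bad = ids[tpm < 0].iloc[0]
        raise ValueError(f"negative TPM for transcript {bad!r} in {path}")
    return dict(zip(ids, tpm))


def expression_divergence_screen(
    pairs: Sequence[OrthologPair],
    exprA: Mapping[str, float],
    exprB: Mapping[str, float],
    ratio_min: float = 50.0,
    max_tpm_min: float = 100.0,
    pseudo: float = 0.01,
    rule: str = "ratio",
) -> list[DivergenceFlag]:
    """Flag ortholog pairs whose expression diverges strongly between species.

    With the default ``rule='ratio'`` a pair is flagged when
    ``(max TPM + pseudo) / (min TPM + pseudo) >= ratio_min`` and the larger
    TPM is at least ``max_tpm_min`` (so pairs that are weakly expressed in
    both species are excluded). ``rule='value'`` instead flags pairs where
    either TPM >= ratio_min unless both are below ``max_tpm_min``. Output is
    sorted by species-A TPM descending.
    """
    if rule not in {"ratio", "value"}:
        raise ValueError(f"unknown screen rule {rule!r}")
    flags = []
    for pair in pairs:
        tpmA = _lookup_tpm(exprA, pair.idA, "A")
        tpmB = _lookup_tpm(exprB, pair.idB, "B")
        hi, lo = max(tpmA, tpmB), min(tpmA, tpmB)
        ratio = (hi + pseudo) / (lo + pseudo)
        if rule == "ratio":
            flagged = ratio >= ratio_min and hi >= max_tpm_min
        else:
            flagged = hi >= ratio_min and not (tpmA < max_tpm_min and tpmB < max_tpm_min)
        flags.append(
            DivergenceFlag(
                idA=pair.idA, idB=pair.idB, tpmA=tpmA, tpmB=tpmB, ratio=ratio, flagged=flagged
            )
        )
    return sorted(flags, key=lambda f: -f.tpmA)


def _lookup_tpm(expr: Mapping[str, float], tid: str, species: str) -> float:
    if tid not in expr:
        warnings.warn(f"transcript {tid!r} missing from species-{species} TPM table; using 0")
        return 0.0
    tpm = float(expr[tid])
    if tpm < 0:
        raise ValueError(f"negative TPM for transcript {tid!r}")
    return tpm


def divergence_table(flags: Sequence[DivergenceFlag]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "idA": f.idA,
                "idB": f.idB,
                "tpmA": f.tpmA,
                "tpmB": f.tpmB,
                "ratio": f.ratio,
                "flagged": f.flagged,
            }
            for f in flags
        ],
        columns=["idA", "idB", "tpmA", "tpmB", "ratio", "flagged"],
    )
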
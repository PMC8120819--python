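"""Mannose-binding-site scanning, region partitioning, substitution profiling,
and rule-based functional prediction for the neoculin protein family.

The family is analysed on mature coordinates (position 1 = first residue after
signal-peptide cleavage). A sequence is partitioned into nine named regions —
N-Pro, N-term, MBS1, inter1, MBS2, inter2, MBS3, C-term, C-Pro — where the
three MBS regions are 9-residue windows matching the GNA-lectin consensus
QxDxNxVxY to varying degrees. Substitutions relative to the basic-subunit
reference are counted per region, each differing column is assigned one of
four categories relative to the two neoculin subunits (and optionally the
lectin-like third reference), and three functional flags are derived per
sequence: heterodimerization (the inter-subunit cysteine pair), lectin
potential (three intact MBS windows), and taste modification (dimerization
plus either the pH-sensing His or the full receptor-activation residue set).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .seq import (
    GAP,
    PairwiseAlignment,
    ProteinRecord,
    ScoringScheme,
    global_align,
    percent_identity,
)

#: Conserved positions of the QxDxNxVxY consensus within a 9-residue window
#: (0-based offset -> required residue).
MBS_PATTERN: dict[int, str] = {0: "Q", 2: "D", 4: "N", 6: "V", 8: "Y"}
MBS_WINDOW = 9

REGION_NAMES = (
    "N-Pro", "N-term", "MBS1", "inter1", "MBS2", "inter2", "MBS3", "C-term", "C-Pro",
)

#: Diagnostic residues on mature basic-subunit numbering.
PH_SITE = 11  # His here confers pH-dependent taste modification
RECEPTOR_SITES: dict[int, str] = {48: "R", 65: "Y", 72: "V", 94: "F"}
DIMER_CYS = (77, 109)  # inter-subunit disulfide pair


@dataclass(frozen=True)
class MotifHit:
    """One MBS-like window on a scanned sequence (1-based start)."""

    start: int
    window: str
    conserved_matches: int

    def __post_init__(self) -> None:
        if len(self.window) != MBS_WINDOW:
            raise ValueError("motif window must be 9 residues")

    @property
    def intact(self) -> bool:
        return self.conserved_matches == len(MBS_PATTERN)

    @property
    def end(self) -> int:
        return self.start + MBS_WINDOW - 1


def scan_mbs_motifs(seq: ProteinRecord, min_conserved: int = 3) -> list[MotifHit]:
    """Find non-overlapping MBS-like windows with >= ``min_conserved`` of the
    five consensus residues.

    All candidate windows are greedily reduced to a non-overlapping set,
    preferring more conserved windows and, on ties, the leftmost. The result
    is sorted by start. Sequences shorter than 9 residues yield an empty list
    with a warning.
    """
    residues = seq.residues
    if len(residues) < MBS_WINDOW:
        warnings.warn(f"sequence {seq.id!r} shorter than {MBS_WINDOW}; no motif scan")
        return []
    candidates = []
    for i in range(len(residues) - MBS_WINDOW + 1):
        window = residues[i : i + MBS_WINDOW]
        matches = sum(1 for off, res in MBS_PATTERN.items() if window[off] == res)
        if matches >= min_conserved:
            candidates.append(MotifHit(start=i + 1, window=window, conserved_matches=matches))
    chosen: list[MotifHit] = []
    for hit in sorted(candidates, key=lambda h: (-h.conserved_matches, h.start)):
        if all(hit.end < c.start or hit.start > c.end for c in chosen):
            chosen.append(hit)
    return sorted(chosen, key=lambda h: h.start)


@dataclass(frozen=True)
class Region:
    """Named contiguous block, 1-based inclusive coordinates; empty if end < start."""

    name: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return max(0, self.end - self.start + 1)

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class RegionPartition:
    """The nine-region partition of a reference precursor.

    Regions are contiguous, non-overlapping, and cover positions
    1..reference length; the three MBS regions are exactly 9 residues; the
    pro-regions may be empty when only mature sequences are analysed.
    """

    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        names = tuple(r.name for r in self.regions)
        if names != REGION_NAMES:
            raise ValueError(f"regions must be named {REGION_NAMES} in order, got {names}")
        cursor = 1
        for region in self.regions:
            if region.length == 0:
                continue
            if region.start != cursor:
                raise ValueError(
                    f"region {region.name} starts at {region.start}, expected {cursor}"
                )
            cursor = region.end + 1
        for name in ("MBS1", "MBS2", "MBS3"):
            if self[name].length != MBS_WINDOW:
                raise ValueError(f"region {name} must have length {MBS_WINDOW}")

    def __getitem__(self, name: str) -> Region:
        for region in self.regions:
            if region.name == name:
                return region
        raise KeyError(name)

    @property
    def reference_length(self) -> int:
        return max(r.end for r in self.regions if r.length > 0)

    def region_of(self, pos: int) -> str:
        for region in self.regions:
            if region.contains(pos):
                return region.name
        raise ValueError(f"position {pos} outside partition (1..{self.reference_length})")

    def mature_region_names(self) -> tuple[str, ...]:
        return tuple(n for n in REGION_NAMES if n not in ("N-Pro", "C-Pro"))


def derive_regions(
    reference: ProteinRecord,
    pro_lengths: tuple[int, int] = (0, 0),
    overrides: Mapping[str, tuple[int, int]] | None = None,
    min_conserved: int = 3,
) -> RegionPartition:
    """Partition a reference precursor into the nine named regions.

    By default the three MBS regions are the three best non-overlapping
    motif windows of the mature sequence in sequence order, and the remaining
    regions tile the gaps between them; the pro-regions come from
    ``pro_lengths``. Explicit ``overrides`` (name -> (start, end), precursor
    coordinates) bypass motif derivation and are validated verbatim.
    """
    if overrides is not None:
        return RegionPartition(
            tuple(Region(name, *overrides[name]) for name in REGION_NAMES)
        )
    n_pro, c_pro = pro_lengths
    mature = reference.residues[n_pro : len(reference) - c_pro]
    hits = scan_mbs_motifs(
        ProteinRecord(reference.id, mature, reference.species), min_conserved=min_conserved
    )
    if len(hits) < 3:
        raise ValueError(
            f"reference {reference.id!r} has only {len(hits)} MBS-like windows at "
            f"min_conserved={min_conserved}; supply explicit region overrides"
        )
    best3 = sorted(
        sorted(hits, key=lambda h: (-h.conserved_matches, h.start))[:3],
        key=lambda h: h.start,
    )
    m1, m2, m3 = best3
    off = n_pro
    regions = (
        Region("N-Pro", 1, n_pro),
        Region("N-term", off + 1, off + m1.start - 1),
        Region("MBS1", off + m1.start, off + m1.end),
        Region("inter1", off + m1.end + 1, off + m2.start - 1),
        Region("MBS2", off + m2.start, off + m2.end),
        Region("inter2", off + m2.end + 1, off + m3.start - 1),
        Region("MBS3", off + m3.start, off + m3.end),
        Region("C-term", off + m3.end + 1, off + len(mature)),
        Region("C-Pro", off + len(mature) + 1, len(reference)),
    )
    return RegionPartition(regions)


def map_reference_position(aln: PairwiseAlignment, ref_pos: int) -> int | None:
    """Query coordinate (1-based) aligned to reference position ``ref_pos``.

    The reference is the *subject* row of the alignment. Returns ``None``
    when the query has a gap in that column.
    """
    n_ref = sum(1 for c in aln.aligned_subject if c != GAP)
    if not (1 <= ref_pos <= n_ref):
        raise ValueError(f"reference position {ref_pos} outside 1..{n_ref}")
    qpos = rpos = 0
    for q, s in zip(aln.aligned_query, aln.aligned_subject):
        if q != GAP:
            qpos += 1
        if s != GAP:
            rpos += 1
            if rpos == ref_pos:
                return qpos if q != GAP else None
    raise AssertionError("unreachable")  # pragma: no cover


def residue_at_reference_position(aln: PairwiseAlignment, ref_pos: int) -> str:
    """Query residue aligned to a reference position, or '-' for a gap."""
    n_ref = sum(1 for c in aln.aligned_subject if c != GAP)
    if not (1 <= ref_pos <= n_ref):
        raise ValueError(f"reference position {ref_pos} outside 1..{n_ref}")
    rpos = 0
    for q, s in zip(aln.aligned_query, aln.aligned_subject):
        if s != GAP:
            rpos += 1
            if rpos == ref_pos:
                return q
    raise AssertionError("unreachable")  # pragma: no cover


def classify_residue_column(
    q: str, nbs: str, nas: str, c9931: str | None = None
) -> str:
    """Category of one aligned column relative to the two subunit references.

    conserved: query matches both subunits; A: matches the acidic subunit
    only; B: matches the basic subunit only; D: matches neither subunit but
    matches the lectin-like third reference; C: matches none of them. A gap
    in the query is treated as an ordinary (non-matching) state.
    """
    if q == nbs == nas:
        return "conserved"
    if q == nas != nbs:
        return "A"
    if q == nbs != nas:
        return "B"
    if c9931 is not None and q == c9931:
        return "D"
    return "C"


@dataclass
class RegionStats:
    name: str
    length: int
    substitutions: int

    @property
    def rate(self) -> float:
        return 100.0 * self.substitutions / self.length if self.length else 0.0


@dataclass
class SubstitutionProfile:
    """Per-region substitution counts/rates of a query against the reference.

    Substitutions are counted on reference coordinates: a column whose
    reference residue lies in a region counts when the query residue differs
    (a query gap counts as a substitution; insertion columns, where the
    reference has a gap, are ignored so region lengths stay fixed to the
    reference). ``categories`` tallies every column's class; the differing
    columns carry exactly one of A/C/D when the reference is the basic
    subunit.
    """

    query_id: str
    reference_id: str
    regions: dict[str, RegionStats]
    categories: dict[str, int]
    overall_substitutions: int
    overall_length: int

    @property
    def overall_rate(self) -> float:
        return 100.0 * self.overall_substitutions / self.overall_length


def substitution_profile(
    query: ProteinRecord,
    reference: ProteinRecord,
    second_ref: ProteinRecord,
    partition: RegionPartition,
    c9931: ProteinRecord | None = None,
    scheme: ScoringScheme | None = None,
) -> SubstitutionProfile:
    """Region-wise substitution profile of ``query`` against ``reference``.

    ``second_ref`` (the other neoculin subunit) and the optional lectin-like
    reference are aligned to the same reference so that each column can be
    categorised with :func:`classify_residue_column`. The overall mature
    count sums the N-term..C-term regions.
    """
    if partition.reference_length != len(reference):
        raise ValueError(
            f"partition covers 1..{partition.reference_length} but reference "
            f"{reference.id!r} has length {len(reference)}"
        )
    aln_q = global_align(query, reference, scheme)
    aln_2 = global_align(second_ref, reference, scheme)
    aln_c = global_align(c9931, reference, scheme) if c9931 is not None else None

    stats = {name: RegionStats(name, partition[name].length, 0) for name in REGION_NAMES}
    categories = {"conserved": 0, "A": 0, "B": 0, "C": 0, "D": 0}
    for pos in range(1, len(reference) + 1):
        region = partition.region_of(pos)
        ref_res = reference.residues[pos - 1]
        q_res = residue_at_reference_position(aln_q, pos)
        nas_res = residue_at_reference_position(aln_2, pos)
        c_res = residue_at_reference_position(aln_c, pos) if aln_c is not None else None
        if q_res != ref_res:
            stats[region].substitutions += 1
        categories[classify_residue_column(q_res, ref_res, nas_res, c_res)] += 1

    mature = [stats[n] for n in partition.mature_region_names()]
    return SubstitutionProfile(
        query_id=query.id,
        reference_id=reference.id,
        regions=stats,
        categories=categories,
        overall_substitutions=sum(s.substitutions for s in mature),
        overall_length=sum(s.length for s in mature),
    )


def profile_long_table(profiles: Sequence[SubstitutionProfile]) -> pd.DataFrame:
    rows = []
    for prof in profiles:
        for name in REGION_NAMES:
            stat = prof.regions[name]
            rows.append(
                {
                    "query": prof.query_id,
                    "region": name,
                    "length": stat.length,
                    "substitutions": stat.substitutions,
                    "rate_percent": round(stat.rate, 2),
                }
            )
    return pd.DataFrame(rows, columns=["query", "region", "length", "substitutions", "rate_percent"])


def profile_heatmap_table(profiles: Sequence[SubstitutionProfile]) -> pd.DataFrame:
    """Wide table of per-region substitution rates (%), one row per query."""
    rows = {}
    for prof in profiles:
        rows[prof.query_id] = {
            name: round(prof.regions[name].rate, 1) for name in REGION_NAMES
        }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(REGION_NAMES))


@dataclass(frozen=True)
class ReferencePanel:
    """Canonical references plus the diagnostic positions on mature numbering."""

    nbs: ProteinRecord
    nas: ProteinRecord
    c9931: ProteinRecord | None = None
    ph_site: int = PH_SITE
    receptor_sites: Mapping[int, str] = field(default_factory=lambda: dict(RECEPTOR_SITES))
    dimer_cys: tuple[int, int] = DIMER_CYS

    def __post_init__(self) -> None:
        n = len(self.nbs)
        diagnostics = [self.ph_site, *self.receptor_sites, *self.dimer_cys]
        if max(diagnostics) > n:
            raise ValueError("diagnostic positions exceed reference length")

    @classmethod
    def from_records(cls, records: Mapping[str, ProteinRecord]) -> "ReferencePanel":
        if "NBS" not in records or "NAS" not in records:
            raise ValueError("reference panel requires the reserved ids NBS and NAS")
        return cls(nbs=records["NBS"], nas=records["NAS"], c9931=records.get("C9931"))


@dataclass
class FunctionalPrediction:
    """Diagnostic residue states and the derived functional flags for one query."""

    query_id: str
    cys_total: int
    has_cys77: bool
    has_cys109: bool
    intact_mbs_count: int
    residue_states: dict[int, str]
    subgroup: str
    dimerization: bool
    lectin_candidate: bool
    taste_modifier: bool
    evidence: str = "canonical"


def functional_prediction(
    query: ProteinRecord,
    panel: ReferencePanel,
    aln_to_nbs: PairwiseAlignment | None = None,
    scheme: ScoringScheme | None = None,
    tpm: float | None = None,
    min_subgroup_identity: float = 60.0,
) -> FunctionalPrediction:
    """Predict dimerization, lectin potential, and taste modification.

    Rules: dimerization requires Cys at the mapped inter-subunit positions
    (77 and 109); lectin potential requires all three MBS windows intact;
    taste modification requires dimerization plus either His at position 11
    or the complete receptor set {Arg-48, Tyr-65, Val-72, Phe-94}. The
    subgroup label is the panel reference with the highest identity, if that
    identity reaches ``min_subgroup_identity`` percent. The evidence
    qualifier is 'canonical' for sequences identical to a panel reference,
    'untested' when the supplied TPM is below 10, otherwise 'probable'.
    """
    if len(query) < 50:
        raise ValueError(
            f"{query.id!r} is only {len(query)} aa; not a plausible family member"
        )
    aln = aln_to_nbs or global_align(query, panel.nbs, scheme)

    diag_positions = sorted({panel.ph_site, *panel.receptor_sites, *panel.dimer_cys})
    states = {pos: residue_at_reference_position(aln, pos) for pos in diag_positions}

    cys77 = states[panel.dimer_cys[0]] == "C"
    cys109 = states[panel.dimer_cys[1]] == "C"
    dimer = cys77 and cys109
    intact = sum(1 for hit in scan_mbs_motifs(query) if hit.intact)
    his = states[panel.ph_site] == "H"
    receptor_ok = all(states[pos] == res for pos, res in panel.receptor_sites.items())
    taste = dimer and (his or receptor_ok)

    refs = {"NBS-like": panel.nbs, "NAS-like": panel.nas}
    if panel.c9931 is not None:
        refs["C9931-like"] = panel.c9931
    identities = {
        label: percent_identity(global_align(query, ref, scheme))
        for label, ref in refs.items()
    }
    best_label, best_ident = max(identities.items(), key=lambda kv: kv[1])
    subgroup = best_label if best_ident >= min_subgroup_identity else "other"

    if any(query.residues == ref.residues for ref in refs.values()):
        evidence = "canonical"
    elif tpm is not None and tpm < 10:
        evidence = "untested"
    else:
        evidence = "probable"

    return FunctionalPrediction(
        query_id=query.id,
        cys_total=query.residues.count("C"),
        has_cys77=cys77,
        has_cys109=cys109,
        intact_mbs_count=intact,
        residue_states=states,
        subgroup=subgroup,
        dimerization=dimer,
        lectin_candidate=intact == 3,
        taste_modifier=taste,
        evidence=evidence,
    )


def predictions_table(predictions: Sequence[FunctionalPrediction]) -> pd.DataFrame:
    """Summary table: one row per query in the dimer/lectin/taste layout."""
    rows = []
    for p in predictions:
        rows.append(
            {
                "query": p.query_id,
                "subgroup": p.subgroup,
                "heterodimerization": f"{'Yes' if p.dimerization else 'No'}({p.cys_total})",
                "lectin_activity": f"{'Yes' if p.lectin_candidate else 'No'}({p.intact_mbs_count})",
                "taste_modification": "Yes" if p.taste_modifier else "No",
                "evidence": p.evidence,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "query", "subgroup", "heterodimerization", "lectin_activity",
            "taste_modification", "evidence",
        ],
    )
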
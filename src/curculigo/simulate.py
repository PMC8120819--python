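"""Synthetic two-species datasets with planted ground truth.

Every pipeline stage can be exercised without any download: a neoculin-like
gene family is grown from the synthetic basic-subunit template by region-wise
random substitution; diagnostic residue states (the mannose-binding-site
consensus slots, the inter-subunit cysteines, the pH-sensing His, the
receptor-activation set) follow explicit per-member plans applied after the
random mutations, so the functional-prediction truth is exact. Ortholog
pairs are planted by mutating each species-A member into its species-B
counterpart at a configured divergence; decoys are composition-preserving
shuffles of the template. TPM values are log-normal, with an optional
anti-correlation mode that gives each ortholog pair one highly and one
weakly expressed side — the expression pattern seen when two related species
have partitioned expression of a duplicated family.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .neoculin import MBS_PATTERN, MBS_WINDOW
from .seq import ProteinRecord, TranscriptRecord, write_fasta
from .synthetic_panel import NBS_MATURE

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

MOTIF_STARTS = (26, 53, 85)  # mature template coordinates of the three windows
DIAGNOSTIC_POSITIONS = (11, 48, 65, 72, 94, 77, 109)

#: Default nine-region substitution probabilities for family growth. The
#: pro-regions are absent (mature template). Values emulate the divergence
#: observed among real family paralogs — roughly 18-27% between the two
#: subunit series and up to ~50% toward the lectin-like series, concentrated
#: between the second motif and the C-terminus — so that paralogs are far
#: more distinct than the ~10% separating a planted ortholog pair.
DEFAULT_REGION_PROBS: dict[str, float] = {
    "N-Pro": 0.0,
    "N-term": 0.10,
    "MBS1": 0.10,
    "inter1": 0.12,
    "MBS2": 0.15,
    "inter2": 0.20,
    "MBS3": 0.15,
    "C-term": 0.20,
    "C-Pro": 0.0,
}

#: Region spans on the mature template (1-based inclusive).
TEMPLATE_REGIONS: dict[str, tuple[int, int]] = {
    "N-Pro": (1, 0),
    "N-term": (1, 25),
    "MBS1": (26, 34),
    "inter1": (35, 52),
    "MBS2": (53, 61),
    "inter2": (62, 84),
    "MBS3": (85, 93),
    "C-term": (94, 114),
    "C-Pro": (115, 114),
}


@dataclass(frozen=True)
class MemberPlan:
    """Planted diagnostic states for one family member.

    ``intact_mbs`` windows (0-3, counted from the first) get all five
    consensus residues; the remaining windows are forced degenerate. The
    boolean fields pin the inter-subunit cysteines, the pH-sensing His-11,
    and the receptor set Arg-48/Tyr-65/Val-72/Phe-94.
    """

    intact_mbs: int = 0
    cys77: bool = True
    cys109: bool = True
    his11: bool = True
    receptor: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.intact_mbs <= 3):
            raise ValueError("intact_mbs must be 0..3")

    @property
    def expects_dimer(self) -> bool:
        return self.cys77 and self.cys109

    @property
    def expects_lectin(self) -> bool:
        return self.intact_mbs == 3

    @property
    def expects_taste(self) -> bool:
        return self.expects_dimer and (self.his11 or self.receptor)


#: Archetypes cycled over family members when no explicit plans are given:
#: a basic-subunit type, an acidic-subunit type, a lectin-candidate type
#: (no dimer cysteines, broken receptor set), and an inert type.
ARCHETYPE_PLANS = (
    MemberPlan(intact_mbs=0, cys77=True, cys109=True, his11=True, receptor=True),
    MemberPlan(intact_mbs=0, cys77=True, cys109=True, his11=False, receptor=True),
    MemberPlan(intact_mbs=3, cys77=False, cys109=False, his11=False, receptor=False),
    MemberPlan(intact_mbs=0, cys77=True, cys109=False, his11=False, receptor=False),
)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic two-species dataset."""

    seed: int = 0
    n_family_members: int = 12
    fraction_orthologs: float = 1.0
    pair_divergence: float = 0.10
    n_decoys: int = 12
    region_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_REGION_PROBS))
    indel_prob: float = 0.0
    plans: tuple[MemberPlan, ...] | None = None
    # TPM model: log-normal components on the natural-log scale
    tpm_high: tuple[float, float] = (float(np.log(1000.0)), 0.5)
    tpm_low: tuple[float, float] = (float(np.log(5.0)), 0.5)
    tpm_base: tuple[float, float] = (float(np.log(10.0)), 1.0)
    anticorrelated_tpm: bool = True

    def __post_init__(self) -> None:
        for name, p in self.region_probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"substitution probability for {name} outside [0,1]: {p}")
        if not (0.0 <= self.fraction_orthologs <= 1.0):
            raise ValueError("fraction_orthologs must lie in [0,1]")
        if not (0.0 <= self.pair_divergence <= 1.0):
            raise ValueError("pair_divergence must lie in [0,1]")
        if self.n_family_members < 0 or self.n_decoys < 0:
            raise ValueError("counts must be non-negative")

    def plan_for(self, index: int) -> MemberPlan:
        if self.plans is not None:
            return self.plans[index % len(self.plans)]
        return ARCHETYPE_PLANS[index % len(ARCHETYPE_PLANS)]


def _protected_positions() -> frozenset[int]:
    """1-based template positions whose state is plan-controlled."""
    protected = set(DIAGNOSTIC_POSITIONS)
    for start in MOTIF_STARTS:
        for off in MBS_PATTERN:
            protected.add(start + off)
    return frozenset(protected)


PROTECTED = _protected_positions()


def _mutate_regionwise(
    residues: list[str], probs: dict[str, float], rng: np.random.Generator
) -> list[str]:
    for name, (start, end) in TEMPLATE_REGIONS.items():
        p = probs.get(name, 0.0)
        if p <= 0 or end < start:
            continue
        for pos in range(start, end + 1):
            if pos in PROTECTED or pos > len(residues):
                continue
            if rng.random() < p:
                choices = [a for a in ALPHABET if a != residues[pos - 1]]
                residues[pos - 1] = choices[rng.integers(len(choices))]
    return residues


def _apply_plan(residues: list[str], plan: MemberPlan) -> list[str]:
    for w, start in enumerate(MOTIF_STARTS):
        if w < plan.intact_mbs:
            for off, res in MBS_PATTERN.items():
                residues[start - 1 + off] = res
        else:
            intact = all(
                residues[start - 1 + off] == res for off, res in MBS_PATTERN.items()
            )
            if intact:  # break one consensus slot so the window stays degenerate
                residues[start - 1 + 8] = "S"
    residues[77 - 1] = "C" if plan.cys77 else "S"
    residues[109 - 1] = "C" if plan.cys109 else "G"
    residues[11 - 1] = "H" if plan.his11 else "Y"
    if plan.receptor:
        for pos, res in {48: "R", 65: "Y", 72: "V", 94: "F"}.items():
            residues[pos - 1] = res
    else:
        residues[48 - 1] = "L"
        residues[94 - 1] = "V"
    return residues


def _apply_indel(residues: list[str], rng: np.random.Generator) -> list[str]:
    """Insert or delete one residue outside motif windows and diagnostics."""
    candidates = [
        pos
        for pos in range(1, len(residues) + 1)
        if pos not in PROTECTED
        and not any(start <= pos < start + MBS_WINDOW for start in MOTIF_STARTS)
    ]
    pos = int(rng.choice(candidates))
    if rng.random() < 0.5 and len(residues) > 60:
        del residues[pos - 1]
    else:
        residues.insert(pos - 1, ALPHABET[rng.integers(len(ALPHABET))])
    return residues


@dataclass
class MemberTruth:
    member_id: str
    plan: MemberPlan
    region_substitutions: dict[str, int]
    had_indel: bool


@dataclass
class SyntheticTruth:
    """Planted ground truth for an emitted dataset."""

    config: SyntheticConfig
    pairs: list[tuple[str, str]] = field(default_factory=list)
    members: dict[str, MemberTruth] = field(default_factory=dict)
    tpm: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        def default(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return dataclasses.asdict(obj)
            raise TypeError(type(obj))  # pragma: no cover

        payload = {
            "config": dataclasses.asdict(self.config),
            "pairs": self.pairs,
            "members": {k: dataclasses.asdict(v) for k, v in self.members.items()},
            "tpm": self.tpm,
        }
        return json.dumps(payload, indent=2, default=default)


def _count_region_substitutions(residues: Sequence[str]) -> dict[str, int]:
    counts = {}
    for name, (start, end) in TEMPLATE_REGIONS.items():
        counts[name] = sum(
            1
            for pos in range(start, min(end, len(residues)) + 1)
            if residues[pos - 1] != NBS_MATURE[pos - 1]
        )
    return counts


def _make_member(
    member_id: str,
    species: str,
    plan: MemberPlan,
    config: SyntheticConfig,
    rng: np.random.Generator,
    base: str = NBS_MATURE,
) -> tuple[ProteinRecord, MemberTruth]:
    residues = _mutate_regionwise(list(base), config.region_probs, rng)
    residues = _apply_plan(residues, plan)
    counts = _count_region_substitutions(residues)
    had_indel = rng.random() < config.indel_prob
    if had_indel:
        residues = _apply_indel(residues, rng)
    record = ProteinRecord(member_id, "".join(residues), species=species)
    return record, MemberTruth(member_id, plan, counts, had_indel)


def generate_family(
    config: SyntheticConfig, species: str = "A", id_prefix: str = "L"
) -> tuple[list[ProteinRecord], SyntheticTruth]:
    """Grow one species' family from the template; reproducible for a seed."""
    rng = np.random.default_rng(config.seed)
    truth = SyntheticTruth(config=config)
    records = []
    for i in range(config.n_family_members):
        member_id = f"{id_prefix}_{i + 1:04d}_c0_g1_i1"
        record, member_truth = _make_member(member_id, species, config.plan_for(i), config, rng)
        records.append(record)
        truth.members[member_id] = member_truth
    return records, truth


def _pair_partner(
    record: ProteinRecord,
    partner_id: str,
    species: str,
    plan: MemberPlan,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[ProteinRecord, MemberTruth]:
    """Derive the other species' ortholog by mutating at the pair divergence."""
    residues = list(record.residues)
    for pos in range(1, len(residues) + 1):
        if pos in PROTECTED:
            continue
        if rng.random() < config.pair_divergence:
            choices = [a for a in ALPHABET if a != residues[pos - 1]]
            residues[pos - 1] = choices[rng.integers(len(choices))]
    residues = _apply_plan(residues, plan)
    rec = ProteinRecord(partner_id, "".join(residues), species=species)
    return rec, MemberTruth(partner_id, plan, _count_region_substitutions(residues), False)


def _decoy(decoy_id: str, species: str, rng: np.random.Generator) -> ProteinRecord:
    shuffled = "".join(rng.permutation(list(NBS_MATURE)))
    return ProteinRecord(decoy_id, shuffled, species=species, description="decoy")


@dataclass
class DatasetBundle:
    """File paths of one generated two-species dataset."""

    proteins_a: Path
    proteins_b: Path
    tpm_a: Path
    tpm_b: Path
    truth: Path


def generate_two_species_dataset(
    config: SyntheticConfig, outdir: str | Path
) -> tuple[DatasetBundle, SyntheticTruth]:
    """Emit FASTA x2, TPM TSV x2, and a JSON truth file under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    truth = SyntheticTruth(config=config)

    records_a: list[ProteinRecord] = []
    records_b: list[ProteinRecord] = []
    n_paired = int(round(config.fraction_orthologs * config.n_family_members))
    for i in range(config.n_family_members):
        plan = config.plan_for(i)
        id_a = f"L_{i + 1:04d}_c0_g1_i1"
        rec_a, truth_a = _make_member(id_a, "C. latifolia", plan, config, rng)
        records_a.append(rec_a)
        truth.members[id_a] = truth_a
        if i < n_paired:
            id_b = f"C_{i + 1:04d}_c0_g1_i1"
            rec_b, truth_b = _pair_partner(rec_a, id_b, "C. capitulata", plan, config, rng)
            records_b.append(rec_b)
            truth.members[id_b] = truth_b
            truth.pairs.append((id_a, id_b))
    # unpaired species-B members keep the family structure but have no partner
    for i in range(n_paired, config.n_family_members):
        id_b = f"C_{i + 1:04d}_c0_g1_i1"
        rec_b, truth_b = _make_member(id_b, "C. capitulata", config.plan_for(i), config, rng)
        records_b.append(rec_b)
        truth.members[id_b] = truth_b
    for i in range(config.n_decoys):
        records_a.append(_decoy(f"L_D{i + 1:03d}_c0_g1_i1", "C. latifolia", rng))
        records_b.append(_decoy(f"C_D{i + 1:03d}_c0_g1_i1", "C. capitulata", rng))

    # TPM draws: each planted pair gets one high and one low side when
    # anti-correlation is on; everything else draws from the base model
    def draw(params: tuple[float, float]) -> float:
        mu, sigma = params
        return float(rng.lognormal(mean=mu, sigma=sigma))

    paired_ids = {i for pair in truth.pairs for i in pair}
    for id_a, id_b in truth.pairs:
        if config.anticorrelated_tpm:
            high, low = draw(config.tpm_high), draw(config.tpm_low)
            if rng.random() < 0.5:
                truth.tpm[id_a], truth.tpm[id_b] = high, low
            else:
                truth.tpm[id_a], truth.tpm[id_b] = low, high
        else:
            truth.tpm[id_a] = draw(config.tpm_base)
            truth.tpm[id_b] = draw(config.tpm_base)
    for rec in records_a + records_b:
        if rec.id not in paired_ids:
            truth.tpm[rec.id] = draw(config.tpm_base)

    bundle = DatasetBundle(
        proteins_a=outdir / "species_a_proteins.fasta",
        proteins_b=outdir / "species_b_proteins.fasta",
        tpm_a=outdir / "species_a_tpm.tsv",
        tpm_b=outdir / "species_b_tpm.tsv",
        truth=outdir / "truth.json",
    )
    if records_a:
        write_fasta(records_a, bundle.proteins_a)
        write_fasta(records_b, bundle.proteins_b)
    else:  # n = 0 still yields valid (empty) files
        bundle.proteins_a.write_text("")
        bundle.proteins_b.write_text("")
    for path, records in ((bundle.tpm_a, records_a), (bundle.tpm_b, records_b)):
        with open(path, "w") as fh:
            fh.write("transcript_id\tTPM\n")
            for rec in records:
                fh.write(f"{rec.id}\t{truth.tpm[rec.id]:.4f}\n")
    bundle.truth.write_text(truth.to_json())
    return bundle, truth


def generate_transcripts(
    n: int, seed: int = 0, mean_log_len: float = 6.6, sigma_log_len: float = 0.6,
    gc: float = 0.45,
) -> list[TranscriptRecord]:
    """Synthetic assembled transcripts with log-normal lengths for summary stats."""
    rng = np.random.default_rng(seed)
    records = []
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    for i in range(n):
        length = max(200, int(rng.lognormal(mean_log_len, sigma_log_len)))
        bases = "".join(rng.choice(list("AGCT"), size=length, p=p))
        records.append(TranscriptRecord(f"T_{i + 1:05d}", bases))
    return records
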
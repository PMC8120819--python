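"""Synthetic neoculin reference panel.

The sequences here are SYNTHETIC stand-ins for the mature neoculin subunits
and their lectin-like relative, constructed so that every documented sequence
relationship of the real proteins holds exactly:

* ``NBS`` (114 aa): His-11; receptor-activation set Arg-48 / Tyr-65 / Val-72 /
  Phe-94; four cysteines including the inter-subunit pair Cys-77 / Cys-109;
  three *degenerate* mannose-binding-site (MBS, QxDxNxVxY) windows starting
  at mature positions 26, 53, and 85 (3, 4, and 3 of the 5 consensus residues
  respectively, so none is intact and the protein has no lectin potential).
* ``NAS`` (113 aa): differs from NBS in exactly 26 of the 114 mature-alignment
  columns (25 substitutions plus one internal deletion), i.e. 77% identity;
  Tyr replaces His at position 11 while the receptor set and all four
  cysteines are retained.
* ``C9931`` (114 aa): the highly expressed lectin-like type — all three MBS
  windows intact (5/5 consensus residues), Tyr-11, Leu at 48 and Val at 94 in
  place of the receptor residues, only two cysteines and neither at 77 nor
  109 (so no heterodimer), and Ser-17 found in no other panel member.

They are NOT the GenBank entries for the real proteins; they encode the
published residue landmarks so that motif scanning, region partitioning,
substitution profiling, and functional prediction are exercised against known
ground truth. Coordinates are mature numbering (position 1 = first residue
after signal-peptide cleavage); the panel carries mature sequences only, so
the N-Pro and C-Pro regions are empty.
"""

from __future__ import annotations

import numpy as np

from .seq import ProteinRecord

# fmt: off
NBS_MATURE = (
    "DNVLLSGQTLHSDGSLAIQNKGNLT"   # N-term 1-25 (His-11, Ala-17)
    "QIDCNRKSW"                   # MBS1 26-34 (degenerate, 3/5; Cys-29)
    "GSACTLTLSEGLVRWENG"          # inter1 35-52 (Cys-38, Arg-48)
    "QPDGNKVTF"                   # MBS2 53-61 (degenerate, 4/5)
    "AGSYALVLQKVDGNACRLTATEW"     # inter2 62-84 (Tyr-65, Val-72, Cys-77)
    "QVDRNGTSH"                   # MBS3 85-93 (degenerate, 3/5)
    "FVIYGPVLWSLGPNGCRRVNG"       # C-term 94-114 (Phe-94, Cys-109)
)
NAS_MATURE = (
    "DSVLLSGQTLYSDGSLGIQNRGNLT"
    "QLDCNRRSW"
    "GSACTLSLDGLVRWQNG"           # one residue shorter: deletion at NBS position 43
    "QSDGNNVTL"
    "AASYTLVLEKVDSNACRLTSTDW"
    "QIDRNGTTH"
    "FVLYAPVLWTLGPDGCRRING"
)
C9931_MATURE = (
    "DDVLLSGQSLYSDGSLSIQNTGNLT"   # Tyr-11, Ser-17
    "QVDNNRVSY"                   # MBS1 intact
    "GSSCTLTLNEGLILFENC"          # Leu-48; Cys-38, Cys-52
    "QADGNTVTY"                   # MBS2 intact
    "PGTYGLILKNVDDNSSRLNASEF"     # Tyr-65, Val-72 kept; no Cys-77
    "QLDRNGVNY"                   # MBS3 intact
    "VVTFGAVIWNLSPKGGRKVQS"       # Val-94; no Cys-109
)
# fmt: on


def reference_panel() -> dict[str, ProteinRecord]:
    """Mature-sequence reference panel keyed by the reserved ids NBS/NAS/C9931."""
    return {
        "NBS": ProteinRecord("NBS", NBS_MATURE, species="C. latifolia",
                             description="synthetic neoculin basic subunit, mature"),
        "NAS": ProteinRecord("NAS", NAS_MATURE, species="C. latifolia",
                             description="synthetic neoculin acidic subunit, mature"),
        "C9931": ProteinRecord("C9931", C9931_MATURE, species="C. capitulata",
                               description="synthetic C_9931-type lectin candidate, mature"),
    }


_MOTIF_CONSERVED_OFFSETS = (0, 2, 4, 6, 8)  # Q.D.N.V.Y within a 9-residue window


def gna_outgroups(n: int = 3, divergence: float = 0.30, seed: int = 20210513) -> list[ProteinRecord]:
    """Synthetic mannose-binding-lectin outgroups for phylogeny examples.

    Each outgroup is the lectin-like panel member further mutated at the given
    per-site rate, but never inside the five consensus positions of its three
    intact MBS windows, so the outgroups stay recognisable lectins.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    protected = set()
    for start in (26, 53, 85):
        for off in _MOTIF_CONSERVED_OFFSETS:
            protected.add(start - 1 + off)
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    out = []
    for k in range(n):
        residues = list(C9931_MATURE)
        for i in range(len(residues)):
            if i in protected:
                continue
            if rng.random() < divergence:
                choices = [a for a in alphabet if a != residues[i]]
                residues[i] = choices[rng.integers(len(choices))]
        out.append(
            ProteinRecord(
                f"GNA_like_{k + 1}",
                "".join(residues),
                species="outgroup",
                description="synthetic GNA-family lectin outgroup",
            )
        )
    return out
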
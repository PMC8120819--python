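"""End-to-end orchestration: proteins + TPM tables in, report tables out.

Stages run in the analysis order: cross-species best hits, reciprocal-best-
hit orthologs, common/unique classification, expression-divergence screen,
neoculin-family scan (substitution profiles + functional predictions for
members similar to the reference panel), anchored MSA + neighbor-joining
tree with bootstrap supports, and the sweetness report. Each stage flushes
its output files as soon as it completes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import orthologs as orth
from . import neoculin as neo
from . import phylo
from . import sweetness as sweet
from .seq import ProteinRecord, ScoringScheme, global_align, percent_identity, read_fasta
from .synthetic_panel import reference_panel


@dataclass
class PipelineConfig:
    """Input paths, thresholds, and run parameters for one pipeline run."""

    proteins_a: str | None = None
    proteins_b: str | None = None
    tpm_a: str | None = None
    tpm_b: str | None = None
    panel_fasta: str | None = None  # reserved ids NBS/NAS/C9931; default synthetic panel
    outdir: str = "curculigo_out"
    min_identity: float = 40.0
    ratio_min: float = 50.0
    max_tpm_min: float = 100.0
    screen_rule: str = "ratio"
    motif_min_conserved: int = 3
    family_min_identity: float = 50.0  # panel similarity needed to enter the family scan
    region_overrides: dict[str, tuple[int, int]] | None = None
    bootstrap_replicates: int = 1000
    seed: int = 42
    sweetness_content: float = sweet.DEFAULT_CONTENT_MG_PER_G
    sweetness_factor: float = sweet.DEFAULT_SWEETNESS_FACTOR
    sweetness_ratio: float = 60.0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """Paths of the emitted report files, keyed by stage."""

    outdir: Path
    files: dict[str, Path] = field(default_factory=dict)


def _load_panel(config: PipelineConfig) -> neo.ReferencePanel:
    if config.panel_fasta:
        records = {r.id: r for r in read_fasta(config.panel_fasta)}
        return neo.ReferencePanel.from_records(records)
    return neo.ReferencePanel.from_records(reference_panel())


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage the inputs allow; returns the report bundle.

    A sweetness-only configuration (no protein paths) is valid and produces
    only the sweetness report. Missing files raise before any computation.
    """
    for attr in ("proteins_a", "proteins_b", "tpm_a", "tpm_b", "panel_fasta"):
        path = getattr(config, attr)
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"{attr}: {path}")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(outdir=outdir)
    log_lines = [
        f"curculigo pipeline, config hash {config.config_hash()}",
        f"seed: {config.seed}",
        f"thresholds: min_identity={config.min_identity} ratio_min={config.ratio_min} "
        f"max_tpm_min={config.max_tpm_min} motif_min_conserved={config.motif_min_conserved} "
        f"family_min_identity={config.family_min_identity} screen_rule={config.screen_rule}",
        f"bootstrap_replicates: {config.bootstrap_replicates}",
    ]
    scheme = ScoringScheme()
    panel = _load_panel(config)

    if config.proteins_a and config.proteins_b:
        set_a = read_fasta(config.proteins_a, species="A")
        set_b = read_fasta(config.proteins_b, species="B")

        hits_ab = orth.best_hits(set_a, set_b, scheme, config.min_identity)
        hits_ba = orth.best_hits(set_b, set_a, scheme, config.min_identity)
        pairs = orth.reciprocal_best_hits(hits_ab, hits_ba)
        log_lines.append(f"orthologs: {len(pairs)} reciprocal best hits")

        classified = orth.classify_genes(set_a, set_b, pairs)
        _write(bundle, "classification", classified.to_csv(sep="\t", index=False))
        _write(
            bundle,
            "classification_summary",
            orth.classification_summary(classified).to_csv(sep="\t", index=False),
        )

        if config.tpm_a and config.tpm_b:
            expr_a = orth.read_expression_table(config.tpm_a)
            expr_b = orth.read_expression_table(config.tpm_b)
            flags = orth.expression_divergence_screen(
                pairs, expr_a, expr_b,
                ratio_min=config.ratio_min,
                max_tpm_min=config.max_tpm_min,
                rule=config.screen_rule,
            )
            _write(bundle, "divergence", orth.divergence_table(flags).to_csv(sep="\t", index=False))
            log_lines.append(f"divergence screen: {sum(f.flagged for f in flags)} flagged")
        else:
            expr_a = expr_b = {}

        pair_rows = "idA\tidB\tidentity\tscore\ttpmA\ttpmB\n" + "".join(
            f"{p.idA}\t{p.idB}\t{p.identity:.2f}\t{p.score:.1f}"
            f"\t{expr_a.get(p.idA, '')}\t{expr_b.get(p.idB, '')}\n"
            for p in pairs
        )
        _write(bundle, "ortholog_pairs", pair_rows)

        # family scan: members similar enough to any panel reference
        family = [
            rec
            for rec in set_a + set_b
            if _panel_identity(rec, panel, scheme) >= config.family_min_identity
        ]
        log_lines.append(f"family scan: {len(family)} panel-similar members")
        if family:
            partition = neo.derive_regions(
                panel.nbs,
                overrides=config.region_overrides,
                min_conserved=config.motif_min_conserved,
            )
            profiles = [
                neo.substitution_profile(rec, panel.nbs, panel.nas, partition, panel.c9931, scheme)
                for rec in family
            ]
            _write(bundle, "profiles_long", neo.profile_long_table(profiles).to_csv(sep="\t", index=False))
            _write(
                bundle,
                "profiles_heatmap",
                neo.profile_heatmap_table(profiles).to_csv(sep="\t", index_label="query"),
            )
            tpms = {**expr_a, **expr_b}
            predictions = [
                neo.functional_prediction(rec, panel, scheme=scheme, tpm=tpms.get(rec.id))
                for rec in family
            ]
            _write(bundle, "predictions", neo.predictions_table(predictions).to_csv(sep="\t", index=False))

        if len(family) >= 3:
            msa = phylo.reference_anchored_msa(family, panel.nbs, scheme)
            tree = phylo.bootstrap_support(
                msa, replicates=config.bootstrap_replicates, seed=config.seed
            )
            _write(bundle, "tree", phylo.write_newick(tree) + "\n", suffix=".nwk")
            dm = phylo.p_distance_matrix(msa)
            _write(bundle, "distances", dm.to_data_frame().to_csv(sep="\t"))

    estimate = sweet.scale_by_expression_ratio(
        config.sweetness_content, config.sweetness_ratio, config.sweetness_factor
    )
    reference_equiv = sweet.sucrose_equivalent(config.sweetness_content, config.sweetness_factor)
    sweet_rows = (
        "quantity\tvalue\tunit\n"
        f"neoculin_content\t{config.sweetness_content}\tmg/g\n"
        f"sweetness_factor\t{config.sweetness_factor}\tfold vs sucrose\n"
        f"sucrose_equivalent\t{reference_equiv:.6g}\tmg/g\n"
        f"expression_ratio\t{config.sweetness_ratio}\tfold\n"
        f"scaled_content\t{sweet.round_sig(estimate.content_mg_per_g * 1000)}\tug/g\n"
        f"scaled_sucrose_equivalent\t{sweet.round_sig(estimate.sucrose_equivalent_mg_per_g)}\tmg/g\n"
    )
    _write(bundle, "sweetness", sweet_rows)

    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    bundle.files["log"] = outdir / "run.log"
    return bundle


def _panel_identity(
    rec: ProteinRecord, panel: neo.ReferencePanel, scheme: ScoringScheme
) -> float:
    refs = [panel.nbs, panel.nas] + ([panel.c9931] if panel.c9931 else [])
    return max(percent_identity(global_align(rec, ref, scheme)) for ref in refs)


def _write(bundle: ReportBundle, name: str, content: str, suffix: str = ".tsv") -> None:
    path = bundle.outdir / f"{name}{suffix}"
    path.write_text(content)
    bundle.files[name] = path
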
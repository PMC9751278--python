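"""End-to-end design pipeline and the canonical gene-box configuration.

``run_pipeline`` composes the full workflow:

    mesh -> edge sizing -> spanning tree -> Eulerian routing -> staples
         -> module plan -> sequences -> module splits -> lid + labels

``canonical_config`` encodes the study conditions of the 50-nm gene-box
cube: 12 edges x 399 bp (19 double turns), two duplexes per edge, 17-nt
unpaired vertex spacers (9984 nt scaffold in total), a 1116-nt unit gene
tiled nine times, modules II and IX split into main + short strands, and a
four-site BamHI lid with Cy3/BHQ2 reporter pairs.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import yaml

from .bundle import DesignBundle, lid_from_dict, make_bundle
from .lid import ContaminationError, apply_lid
from .mesh import (
    DEFAULT_RISE_NM_PER_BP,
    PolyhedralMesh,
    build_cube_mesh,
    load_and_validate_mesh,
    size_edges,
)
from .routing import compute_spanning_tree, route_scaffold
from .seqplan import (
    GeneUnit,
    apply_sequences,
    load_gene_fasta,
    plan_modules,
    split_module_scaffolds,
)
from .staples import assign_staples_to_modules, generate_staples
from .synth import synth_gene

__all__ = ["ConfigError", "PipelineConfig", "canonical_config", "run_pipeline"]

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Structured pipeline configuration (YAML-serializable)."""

    seed: int = 7
    mesh_ply: str | None = None            # path to a PLY file, or ...
    cube_edge_bp: int | None = None        # ... build a cube sized from bp
    edge_bp: int | dict = 399              # target bp per edge
    spacer_nt: int = 17
    rise_nm_per_bp: float = DEFAULT_RISE_NM_PER_BP
    gene_fasta: str | None = None
    synth: dict | None = None              # {"length", "gc_fraction"}
    splits: dict = field(default_factory=dict)
    lid: dict | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def canonical_config(seed: int = 7) -> PipelineConfig:
    """The canonical endogenous-gene cube ("gene-box") study conditions."""
    return PipelineConfig(
        seed=seed,
        cube_edge_bp=399,
        edge_bp=399,
        spacer_nt=17,
        synth={"length": 1116, "gc_fraction": 0.44},
        splits={
            "II": {
                "windows": [
                    [1117, 1196, "Scaffold-2α"],
                    [1197, 1280, "Scaffold-2β"],
                    [1281, 1340, "Scaffold-2γ"],
                    [1341, 1420, "Scaffold-2δ"],
                ],
                "main_name": "Scaffold-2M",
            },
            "IX": {
                "windows": [[8929, 8950, "Scaffold-9α"]],
                "main_name": "Scaffold-9M",
            },
        },
        lid={
            "enzyme_name": "BamHI",
            "motif": "GGATCC",
            "cut_offset_top": 1,
            "cut_offset_bottom": 5,
            "site_anchors": [[1197, 1202], [1281, 1286], [1405, 1410], [8945, 8950]],
            "label_pairs": [
                {"pair_id": 1, "fluor_dye": "Cy3", "fluor_pos": 8933,
                 "quencher_dye": "BHQ2", "quencher_pos": 1346},
                {"pair_id": 2, "fluor_dye": "Cy3", "fluor_pos": 1001,
                 "quencher_dye": "BHQ2", "quencher_pos": 1194},
            ],
        },
    )


def _resolve_mesh(cfg: PipelineConfig) -> PolyhedralMesh:
    if cfg.mesh_ply:
        return load_and_validate_mesh(cfg.mesh_ply)
    if cfg.cube_edge_bp:
        return build_cube_mesh(cfg.cube_edge_bp * cfg.rise_nm_per_bp)
    raise ConfigError("config needs either mesh_ply or cube_edge_bp")


def _resolve_gene(cfg: PipelineConfig, attempt: int = 0) -> GeneUnit:
    if cfg.gene_fasta:
        return load_gene_fasta(cfg.gene_fasta)
    if cfg.synth:
        motif = (cfg.lid or {}).get("motif", "GGATCC")
        seed = (cfg.seed + attempt * 1_000_003) % (2**31)
        return synth_gene(
            length=cfg.synth["length"],
            gc_fraction=cfg.synth.get("gc_fraction", 0.44),
            forbidden_motifs=(motif,),
            seed=seed,
        )
    raise ConfigError("config needs either gene_fasta or a synth block")


def run_pipeline(config: PipelineConfig) -> DesignBundle:
    """Execute the full design workflow and return the bundle."""
    try:
        mesh = _resolve_mesh(config)
    except ConfigError:
        raise
    except Exception as exc:
        raise ConfigError(f"mesh stage failed: {exc}") from exc
    log.info("mesh: %d vertices, %d edges, %d faces",
             mesh.n_vertices, mesh.n_edges, mesh.n_faces)

    plans = size_edges(mesh, config.edge_bp)
    tree = compute_spanning_tree(mesh)
    routing = route_scaffold(mesh, plans, tree, spacer_nt=config.spacer_nt)
    log.info("routing: %d duplex traversals, %d crossover edges, %d nt total",
             routing.n_traversals, len(routing.crossover_edges), routing.total_nt)

    staples = generate_staples(routing, plans)
    log.info("staples: %d strands, %d nt", len(staples.staples), staples.total_nt)

    lid_spec = lid_from_dict(config.lid)
    for attempt in range(5):
        unit = _resolve_gene(config, attempt)
        plan = plan_modules(unit, routing.total_nt)
        split_spec = {
            numeral: {
                "windows": [tuple(w) for w in spec["windows"]],
                "main_name": spec.get("main_name", ""),
            }
            for numeral, spec in config.splits.items()
        }
        for numeral, spec in split_spec.items():
            if not spec["main_name"]:
                del spec["main_name"]
        plan = split_module_scaffolds(plan, split_spec) if split_spec else plan
        staples_assigned = assign_staples_to_modules(
            staples, plan.module_boundaries()
        )
        design = apply_sequences(
            plan, unit, routing, staples_assigned,
            mesh=mesh, plans=tuple(plans), tree=tree,
        )
        try:
            if lid_spec is not None:
                design = apply_lid(design, lid_spec)
            break
        except ContaminationError:
            if config.gene_fasta or attempt == 4:
                raise
            # a tiling junction produced a stray motif hit; draw a fresh gene
            log.warning("gene attempt %d contaminated at a junction; retrying",
                        attempt)
    log.info(
        "plan: %d modules, %d strands; lid: %s sites",
        plan.cycles,
        sum(len(m.strands) for m in plan.modules),
        len(lid_spec.site_anchors) if lid_spec else 0,
    )
    return make_bundle(design, config.to_dict(), config.seed)
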
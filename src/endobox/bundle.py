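"""Design-bundle serialization: one structured JSON document.

The bundle ties together everything the pipeline produced -- mesh, edge
plans, routing, multiscaffold plan, staples, lid, and provenance (config
hash, seed, tool version) -- in a diffable, language-neutral form that
round-trips losslessly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

from . import __version__
from .lid import LabelPair, LidSpec
from .mesh import EdgePlan, PolyhedralMesh
from .routing import DuplexTraversal, ScaffoldRouting
from .seqplan import (
    Design,
    GeneUnit,
    ModuleSpan,
    MultiscaffoldPlan,
    StrandSpan,
)
from .staples import Decoration, StapleRecord, StapleSegment, StapleSet

__all__ = ["DesignBundle", "bundle_to_dict", "bundle_from_dict",
           "save_bundle", "load_bundle", "config_hash"]

SCHEMA_VERSION = 1


def config_hash(config_dict: dict) -> str:
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class DesignBundle:
    design: Design
    provenance: dict

    def __eq__(self, other):
        if not isinstance(other, DesignBundle):
            return NotImplemented
        return bundle_to_dict(self) == bundle_to_dict(other)


def make_bundle(design: Design, config_dict: dict, seed: int) -> DesignBundle:
    return DesignBundle(
        design=design,
        provenance={
            "config_hash": config_hash(config_dict),
            "seed": seed,
            "tool_version": __version__,
        },
    )


def _lid_to_dict(lid: LidSpec | None):
    if lid is None:
        return None
    return {
        "enzyme_name": lid.enzyme_name,
        "motif": lid.motif,
        "cut_offset_top": lid.cut_offset_top,
        "cut_offset_bottom": lid.cut_offset_bottom,
        "site_anchors": [list(a) for a in lid.site_anchors],
        "label_pairs": [
            {
                "pair_id": p.pair_id,
                "fluor_dye": p.fluor_dye,
                "fluor_pos": p.fluor_pos,
                "quencher_dye": p.quencher_dye,
                "quencher_pos": p.quencher_pos,
            }
            for p in lid.label_pairs
        ],
    }


def lid_from_dict(d: dict | None) -> LidSpec | None:
    if d is None:
        return None
    return LidSpec(
        enzyme_name=d["enzyme_name"],
        motif=d["motif"],
        cut_offset_top=d["cut_offset_top"],
        cut_offset_bottom=d["cut_offset_bottom"],
        site_anchors=tuple(tuple(a) for a in d["site_anchors"]),
        label_pairs=tuple(LabelPair(**p) for p in d["label_pairs"]),
    )


def bundle_to_dict(bundle: DesignBundle) -> dict:
    d = bundle.design
    return {
        "schema_version": SCHEMA_VERSION,
        "provenance": dict(bundle.provenance),
        "mesh": {
            "vertices": d.mesh.vertices.tolist(),
            "faces": [list(f) for f in d.mesh.faces],
        },
        "plans": [
            {
                "edge_id": p.edge_id, "raw_bp": p.raw_bp, "final_bp": p.final_bp,
                "extension": p.extension, "fallback": p.fallback,
            }
            for p in d.plans
        ],
        "tree": sorted(d.tree),
        "routing": {
            "spacer_nt": d.routing.spacer_nt,
            "circuit": [
                [tr.edge_id, tr.duplex, tr.start_vertex, tr.end_vertex, tr.bp]
                for tr in d.routing.circuit
            ],
        },
        "unit": {"id": d.unit.id, "sequence": d.unit.sequence},
        "msplan": {
            "total_nt": d.msplan.total_nt,
            "cycles": d.msplan.cycles,
            "trim_upstream_nt": d.msplan.trim_upstream_nt,
            "trim_downstream_nt": d.msplan.trim_downstream_nt,
            "modules": [
                {
                    "numeral": m.numeral, "index": m.index,
                    "start": m.start, "end": m.end,
                    "strands": [
                        {"name": s.name, "start": s.start, "end": s.end,
                         "kind": s.kind}
                        for s in m.strands
                    ],
                }
                for m in d.msplan.modules
            ],
        },
        "staples": [
            {
                "name": r.name,
                "segments": [
                    [s.edge_id, s.duplex, s.start_offset, s.end_offset]
                    for s in r.segments
                ],
                "footprint": list(r.footprint),
                "modules": sorted(r.modules),
                "shared": r.shared,
                "decorations": [
                    {"dye": deco.dye, "nt_index": deco.nt_index,
                     "role": deco.role, "pair_id": deco.pair_id,
                     "scaffold_pos": deco.scaffold_pos}
                    for deco in r.decorations
                ],
            }
            for r in d.staples.staples
        ],
        "scaffold_seq": d.scaffold_seq,
        "lid": _lid_to_dict(d.lid),
    }


def bundle_from_dict(data: dict) -> DesignBundle:
    if data.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported bundle schema {data.get('schema_version')!r}")
    mesh = PolyhedralMesh.from_data(data["mesh"]["vertices"], data["mesh"]["faces"])
    plans = tuple(
        EdgePlan(edge_id=p["edge_id"], raw_bp=p["raw_bp"], final_bp=p["final_bp"],
                 extension=p["extension"], fallback=p["fallback"])
        for p in data["plans"]
    )
    routing = ScaffoldRouting(
        circuit=tuple(
            DuplexTraversal(edge_id=c[0], duplex=c[1], start_vertex=c[2],
                            end_vertex=c[3], bp=c[4])
            for c in data["routing"]["circuit"]
        ),
        crossover_edges=frozenset(range(mesh.n_edges)) - frozenset(data["tree"]),
        spacer_nt=data["routing"]["spacer_nt"],
        total_nt=sum(c[4] for c in data["routing"]["circuit"])
        + len(data["routing"]["circuit"]) * data["routing"]["spacer_nt"],
    )
    unit = GeneUnit(id=data["unit"]["id"], sequence=data["unit"]["sequence"])
    mp = data["msplan"]
    msplan = MultiscaffoldPlan(
        unit_id=unit.id,
        unit_length=unit.length,
        total_nt=mp["total_nt"],
        cycles=mp["cycles"],
        trim_upstream_nt=mp["trim_upstream_nt"],
        trim_downstream_nt=mp["trim_downstream_nt"],
        modules=tuple(
            ModuleSpan(
                numeral=m["numeral"], index=m["index"],
                start=m["start"], end=m["end"],
                strands=tuple(StrandSpan(**s) for s in m["strands"]),
            )
            for m in mp["modules"]
        ),
    )
    staples = StapleSet(
        staples=tuple(
            StapleRecord(
                name=r["name"],
                segments=tuple(
                    StapleSegment(edge_id=s[0], duplex=s[1],
                                  start_offset=s[2], end_offset=s[3])
                    for s in r["segments"]
                ),
                footprint=tuple(r["footprint"]),
                modules=frozenset(r["modules"]),
                shared=r["shared"],
                decorations=tuple(Decoration(**deco) for deco in r["decorations"]),
            )
            for r in data["staples"]
        )
    )
    design = Design(
        mesh=mesh,
        plans=plans,
        tree=frozenset(data["tree"]),
        routing=routing,
        unit=unit,
        msplan=msplan,
        staples=staples,
        scaffold_seq=data["scaffold_seq"],
        lid=lid_from_dict(data["lid"]),
    )
    return DesignBundle(design=design, provenance=data["provenance"])


def save_bundle(bundle: DesignBundle, path) -> None:
    with open(path, "w") as fh:
        json.dump(bundle_to_dict(bundle), fh, indent=1)
        fh.write("\n")


def load_bundle(path) -> DesignBundle:
    with open(path) as fh:
        return bundle_from_dict(json.load(fh))
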
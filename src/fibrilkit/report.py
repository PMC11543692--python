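"""End-to-end analysis of one fibril model: geometry, bonds, contacts,
cavities, consensus scoring and (optionally) trajectory separation, with all
cutoffs centralized and logged."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import cavities as cav
from . import contacts as con
from .consensus import consensus as build_consensus
from .consensus import read_track
from . import geometry as geo
from . import separation as sep
from .model import FibrilModel, read_structure

log = logging.getLogger("fibrilkit")

#: Central default table; every cutoff used anywhere in the pipeline.
DEFAULTS = {
    "disulfide_cutoff_A": 2.5,
    "contact_cutoff_A": 4.5,
    "ion_pair_cutoff_A": 4.0,
    "hydrophobic_cutoff_A": 5.0,
    "hydrophobic_min_size": 3,
    "cavity_probe_A": 1.4,
    "cavity_spacing_A": 0.5,
    "cavity_min_volume_A3": 20.0,
    "cavity_shell_A": 4.5,
    "sasa_buried_threshold": 0.15,
    "sasa_probe_A": 1.4,
    "sasa_points": 960,
    "width_margin_A": 1.5,
    "loosening_threshold_nm": 0.7,
    "burnin_ns": 50.0,
}


@dataclass
class RunConfig:
    structure: Optional[str] = None
    trajectories: list[str] = field(default_factory=list)
    tracks: list[str] = field(default_factory=list)
    twist: Optional[float] = None
    rise: Optional[float] = None
    layer_pair: Optional[tuple[int, int]] = None
    out_dir: str = "fibril_report"
    seed: int = 0
    cutoffs: dict = field(default_factory=lambda: dict(DEFAULTS))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cut = dict(DEFAULTS)
        cut.update(data.pop("cutoffs", {}))
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        cfg.cutoffs = cut
        return cfg


def run_full_analysis(config: RunConfig) -> dict:
    """Run every applicable analysis stage; write CSV/JSON outputs.

    Returns the summary dict (also written to summary.json). Stage failures
    raise; partial outputs written before the failure are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    c = config.cutoffs
    for k, v in sorted(c.items()):
        log.info("cutoff %s = %s", k, v)
    summary: dict = {"config": {k: v for k, v in asdict(config).items() if k != "cutoffs"},
                     "cutoffs": dict(c)}

    model: Optional[FibrilModel] = None
    if config.structure:
        log.info("stage: read structure %s", config.structure)
        model = read_structure(config.structure)
        summary["n_layers"] = model.n_layers
        summary["n_residues_per_layer"] = len(model.layers[0].residues)

        log.info("stage: helical geometry")
        if config.twist is not None and config.rise is not None:
            params = geo.HelicalParams(config.twist, config.rise)
        elif model.n_layers >= 2:
            params = geo.estimate_params(model)
        else:
            params = None
        if params is not None:
            gsum = geo.summarize_geometry(model, params, width_margin=c["width_margin_A"])
            geometry = {"twist_deg": params.twist, "rise_A": params.rise,
                        **gsum.to_dict()}
            (out / "geometry.json").write_text(json.dumps(geometry, indent=2))
            summary["geometry"] = geometry

        log.info("stage: disulfides")
        bonds = con.detect_disulfides(model, cutoff=c["disulfide_cutoff_A"])
        pd.DataFrame(
            [
                {"chain_a": b.residue_a[0], "seq_a": b.residue_a[1],
                 "chain_b": b.residue_b[0], "seq_b": b.residue_b[1],
                 "sg_distance_A": b.sg_distance}
                for b in bonds
            ]
        ).to_csv(out / "disulfides.csv", index=False)
        summary["n_disulfides"] = len(bonds)

        if model.n_layers >= 3:
            log.info("stage: layer contacts")
            mid = model.layers[model.n_layers // 2].layer_index
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                edges = con.layer_contacts(model, mid, cutoff=c["contact_cutoff_A"])
            pd.DataFrame(
                [{"layer_i": e.layer_i, "layer_j": e.layer_j,
                  "n_pairs": e.n_atom_pairs, "min_dist_A": e.min_distance}
                 for e in edges]
            ).to_csv(out / "contacts.csv", index=False)
            summary["n_contacting_layers"] = len(edges)

        log.info("stage: ion pairs")
        pairs = con.find_ion_pairs(model, cutoff=c["ion_pair_cutoff_A"])
        pd.DataFrame(
            [{"acidic": f"{p.acidic[0]}/{p.acidic[2]}{p.acidic[1]}",
              "basic": f"{p.basic[0]}/{p.basic[2]}{p.basic[1]}",
              "distance_A": p.distance, "same_layer": p.same_layer}
             for p in pairs]
        ).to_csv(out / "ion_pairs.csv", index=False)
        summary["n_ion_pairs"] = len(pairs)

        log.info("stage: hydrophobic clusters")
        clusters = con.hydrophobic_clusters(
            model, cutoff=c["hydrophobic_cutoff_A"], min_size=c["hydrophobic_min_size"]
        )
        pd.DataFrame(
            [{"cluster": i, "size": len(cl),
              "residues": ";".join(f"{ch}{sq}" for ch, sq in sorted(cl))}
             for i, cl in enumerate(clusters)]
        ).to_csv(out / "clusters.csv", index=False)
        summary["n_hydrophobic_clusters"] = len(clusters)

        if model.n_layers >= 5:
            log.info("stage: cavities")
            found = cav.detect_cavities(
                model, probe=c["cavity_probe_A"], spacing=c["cavity_spacing_A"],
                min_volume=c["cavity_min_volume_A3"],
            )
            rise = params.rise if params is not None else 4.8
            rows = []
            for i, cavity in enumerate(found):
                pol = cav.cavity_polarity(cavity, model, shell=c["cavity_shell_A"])
                zc = cav.z_continuity(cavity, rise, spacing=c["cavity_spacing_A"])
                rows.append({"cavity": i, "volume_A3": cavity.volume, "polarity": pol,
                             "z_continuous": zc,
                             "lining": ";".join(f"{ch}{sq}" for ch, sq, _ in
                                                sorted(cavity.lining_residues))})
            pd.DataFrame(rows).to_csv(out / "cavities.csv", index=False)
            summary["n_cavities"] = len(found)

    if config.tracks:
        log.info("stage: aggregation consensus")
        tracks = [read_track(p) for p in config.tracks]
        profile = build_consensus(tracks)
        pd.DataFrame(
            {"residue_seq": range(1, len(profile) + 1),
             "consensus": profile.values, "color": profile.colors()}
        ).to_csv(out / "consensus.csv", index=False)
        summary["consensus_max"] = int(profile.values.max())
        summary["n_consensus_hits"] = int((profile.values > 0).sum())

    if config.trajectories:
        log.info("stage: layer separation")
        trajs = [sep.read_multimodel_pdb(p, dt_ns=1.0, replica_id=i)
                 for i, p in enumerate(config.trajectories)]
        if config.layer_pair is not None:
            pair = tuple(config.layer_pair)
        else:
            n = trajs[0].topology.n_layers
            pair = (n - 2, n - 1)  # tip pair
        prof = sep.separation_profile(trajs, pair, burnin_ns=c["burnin_ns"])
        flagged, regions = sep.flag_loosened(prof, threshold_nm=c["loosening_threshold_nm"])
        df = prof.to_frame()
        df["flagged"] = [int(r) in flagged for r in df.index]
        df.to_csv(out / "separation.csv")
        pd.DataFrame(regions, columns=["start", "end"]).to_csv(
            out / "regions.csv", index=False)
        summary["loosened_regions"] = regions
        summary["layer_pair"] = list(pair)

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    log.info("summary written to %s", out / "summary.json")
    return summary
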
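"""End-to-end workflows: the tether-dimerisation pipeline and geometry report.

The tether pipeline runs the full chain — build (or load) the model,
assemble contact maps with any configured crystal-contact exclusions, dock
or adopt the docked reference, scale the interface strength, build the
forcefield, minimise, simulate, and analyse — and persists every artefact
plus a provenance manifest (parameters, seeds, versions, input checksums)
into the output directory.

The default simulation start is the minimised docked reference: at desk
scale both unbinding and rebinding of the tethered domains are then
observable within the trial budget, which a first-encounter-limited start
would not allow.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from . import analysis as ana
from . import forcefield as ffm
from .contacts import ContactMap, write_contacts
from .dynamics import SimulationParams, langevin_run
from .structure import save_trajectory, write_bead_pdb
from .synthetic import ToySpec, make_tethered_pair, bead_index, domain_maps

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Declarative configuration for the tether pipeline (toy system).

    ``interface_strength`` is the fraction of the native contact strength
    given to the heterodimer interface contacts (0.5 is the reference
    condition at which the tetramer populated the dimerised state half
    the time).  ``excluded_contacts`` lists residue-id pairs to drop from
    the assembled map, mirroring the removal of crystal-packing contacts.
    """

    toy: dict = field(default_factory=dict)
    interface_strength: float = 0.5
    start_from: str = "docked"            # "docked" | "separated"
    exclude_contacts: list = field(default_factory=list)  # [[res_a, res_b], ...]
    simulation: dict = field(default_factory=dict)
    n_runs: int = 1                       # independent trajectories pooled
    burn_in: float = ana.DEFAULT_BURN_IN
    q_threshold: float = ana.DEFAULT_Q_THRESHOLD
    d_threshold: float = ana.DEFAULT_DISTANCE_THRESHOLD
    bins: int = 40
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        import yaml

        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ConfigError(f"unknown configuration keys: {sorted(bad)}")
        return cls(**data)

    def to_yaml(self) -> str:
        import yaml

        return yaml.safe_dump(asdict(self), sort_keys=True)


def _checksum(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def run_tether_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute the full tethered-dimerisation workflow.

    Returns a results dict (trajectory, series, occupancy under both
    classification rules, free-energy surfaces, manifest).  When an output
    directory is given, all artefacts are persisted there, including the
    verbatim configuration and a manifest; partial outputs survive a
    failed stage.
    """
    out = Path(outdir or config.outdir) if (outdir or config.outdir) else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.yaml").write_text(config.to_yaml())
    results: dict = {}

    def stage(name):
        logger.info("stage %s", name)

        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise StageError(name, exc) from exc

        return wrap

    pair = stage("build")(lambda: make_tethered_pair(ToySpec(**config.toy)))
    results["pair"] = pair
    logger.info("built toy system: %d beads, %d intra contacts, %d interface",
                len(pair.docked), len(pair.intra_map), len(pair.interface_map))

    def assemble_maps():
        intra = pair.intra_map
        if config.exclude_contacts:
            drop = {frozenset(map(tuple, p)) if isinstance(p[0], (list, tuple))
                    else frozenset((("T", int(p[0])), ("T", int(p[1]))))
                    for p in config.exclude_contacts}
            kept = [c for c in intra if c.unordered() not in drop]
            removed = len(intra) - len(kept)
            logger.info("removed %d excluded contact(s) from the intra map",
                        removed)
            intra = ContactMap(kept, intra.provenance, dict(intra.parameters))
        iface = pair.interface_map.scaled(config.interface_strength, "interface")
        return intra, iface

    intra_map, iface_map = stage("contacts")(assemble_maps)
    if out is not None:
        (out / "intra_contacts.txt").write_text(write_contacts(intra_map))
        (out / "interface_contacts.txt").write_text(write_contacts(iface_map))

    ff = stage("forcefield")(
        lambda: ffm.build_forcefield(pair.docked, intra_map, iface_map))
    if out is not None:
        (out / "topology.txt").write_text(ffm.write_topology(ff))

    start = (pair.docked.coord if config.start_from == "docked"
             else pair.start.coord)
    x0 = stage("minimise")(lambda: ffm.minimize(ff, start, force_tol=1e-3))

    sim = SimulationParams(seed=config.seed, **config.simulation)

    def simulate():
        trajs = []
        for run in range(max(1, int(config.n_runs))):
            p = dataclasses.replace(sim, seed=sim.seed + run)
            trajs.append(langevin_run(ff, x0, p))
        return trajs

    trajs = stage("simulate")(simulate)
    traj = trajs[0]
    results["trajectory"] = traj
    if out is not None:
        save_trajectory(out / "trajectory.bin", traj.frames, sim.stride, sim.seed)
        (out / "start.pdb").write_text(
            write_bead_pdb(pair.docked.with_coords(x0)))

    def analyse():
        bi = bead_index(pair.docked)
        q_runs, d_runs = [], []
        for t in trajs:
            q_runs.append(ana.interface_q_series(t, pair.interface_map, bi))
            d_runs.append(ana.com_distance_series(
                t, pair.marker_groups["A"], pair.marker_groups["B"]))
        # per-run burn-in, then pool across the independent trajectories
        if len(trajs) == 1:
            q, d = q_runs[0], d_runs[0]
        else:
            def pooled(runs, kind):
                start = int(np.floor(config.burn_in * len(runs[0])))
                return ana.CoordinateSeries(
                    np.concatenate([r.values[start:] for r in runs]), kind)
            q, d = pooled(q_runs, "q_interface"), pooled(d_runs, "distance")
        burn = config.burn_in if len(trajs) == 1 else 0.0
        occ_q = ana.occupancy(q, rule="q", q_threshold=config.q_threshold,
                              burn_in=burn, seed=config.seed)
        occ_d = ana.occupancy(d, rule="distance",
                              d_threshold=config.d_threshold,
                              burn_in=burn, seed=config.seed)
        fes_q = ana.free_energy_surface(q, bins=config.bins,
                                        temperature=sim.temperature)
        fes_2d = ana.free_energy_surface((d, q), bins=config.bins,
                                         temperature=sim.temperature)
        return dict(q_series=q, d_series=d, occupancy_q=occ_q,
                    occupancy_d=occ_d, fes_q=fes_q, fes_2d=fes_2d)

    results.update(stage("analyse")(analyse))

    manifest = {
        "package_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config_checksum": _checksum(config.to_yaml()),
        "seed": config.seed,
        "simulation": asdict(sim),
        "n_beads": len(pair.docked),
        "n_intra_contacts": len(intra_map),
        "n_interface_contacts": len(iface_map),
        "interface_strength": config.interface_strength,
        "occupancy_q": asdict(results["occupancy_q"]),
        "occupancy_d": asdict(results["occupancy_d"]),
    }
    results["manifest"] = manifest
    if out is not None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        _write_series_tsv(out / "series.tsv", results)
    return results


def _write_series_tsv(path: Path, results: dict) -> None:
    import pandas as pd

    q, d = results["q_series"], results["d_series"]
    pd.DataFrame({
        "frame": q.frame_indices,
        "marker_distance_A": d.values,
        "q_interface": q.values,
    }).to_csv(path, sep="\t", index=False)


def evaluate_strength(config: RunConfig, factor: float,
                      seed: int | None = None) -> ana.OccupancyResult:
    """One tuning trial: run the pipeline at the given interface strength
    and return its Q-rule occupancy."""
    trial = dataclasses.replace(config, interface_strength=float(factor),
                                seed=config.seed if seed is None else seed,
                                outdir=None)
    res = run_tether_pipeline(trial)
    return res["occupancy_q"]


def tune_pipeline_strength(config: RunConfig, target: float = 0.5,
                           **kwargs) -> ana.TuneResult:
    """Bisect the interface strength of the configured pipeline to a
    target occupancy (the computational counterpart of choosing the
    interface half as strong as the native contacts to populate the
    dimerised state half the time)."""
    return ana.tune_interface_strength(
        lambda f: evaluate_strength(config, f), target=target, **kwargs)


# ---------------------------------------------------------------------------
# geometry report


def run_geometry_report(structure, requests: list[dict]) -> list[dict]:
    """Evaluate a list of geometry requests against a structure.

    Each request is a dict with ``kind`` in {"sasa", "bsa", "rmsd",
    "hinge", "reach"} plus the kind's parameters (selections in the
    chain/residue mini-language, coordinate arrays for rmsd/hinge, a
    segment path for reach).  Returns one result dict per request with
    the convention stated inline.  An empty request list yields an empty
    report.
    """
    from . import geometry as geo

    report = []
    for req in requests:
        kind = req["kind"]
        if kind == "sasa":
            mask = (geo.parse_selection(structure, req["selection"])
                    if "selection" in req else np.ones(len(structure), bool))
            _, total = geo.sasa(structure.subset(mask),
                                req.get("probe_radius", geo.DEFAULT_PROBE_RADIUS))
            report.append({"kind": kind, "total_A2": total,
                           "convention": "Shrake–Rupley, probe 1.4 Å"})
        elif kind == "bsa":
            rep = geo.buried_surface_area(
                structure,
                geo.parse_selection(structure, req["part_a"]),
                geo.parse_selection(structure, req["part_b"]),
                req.get("probe_radius", geo.DEFAULT_PROBE_RADIUS))
            report.append({
                "kind": kind,
                "bsa_two_sided_A2": rep.bsa_two_sided,
                "bsa_one_sided_A2": rep.bsa_one_sided,
                "convention": "two-sided = SASA(A)+SASA(B)-SASA(AB); "
                              "one-sided = half",
            })
        elif kind == "rmsd":
            report.append({"kind": kind, "rmsd_A": geo.rmsd_after_superposition(
                np.asarray(req["mobile"]), np.asarray(req["reference"]))})
        elif kind == "hinge":
            angle, axis, screw = geo.hinge_angle(
                np.asarray(req["ref_state1"]), np.asarray(req["ref_state2"]),
                np.asarray(req["mov_state1"]), np.asarray(req["mov_state2"]))
            report.append({"kind": kind, "angle_deg": angle,
                           "axis": list(axis), "screw_A": screw})
        elif kind == "reach":
            report.append({"kind": kind, **geo.max_reach(req["segments"])})
        else:
            raise ConfigError(f"unknown geometry request kind {kind!r}")
    return report
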
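"""Langevin dynamics in reduced units.

Integration uses a BAOAB-style Langevin leapfrog: bead mass 1, Boltzmann
constant 1, energies in units of the contact strength ε.  The reference
regime is a dimensionless timestep of 0.0005, a thermostat coupling
(friction) of 1, and a reduced temperature T* = 0.92 — low enough that
individually folded domains stay folded, high enough to sample reversible
heterodimerisation.  With zero friction and zero temperature the scheme
reduces to velocity Verlet and conserves energy.

Runs are bit-reproducible for a given seed and parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import _kernels
from .forcefield import ForceField, ForceFieldError

DEFAULT_TIMESTEP = 0.0005
DEFAULT_FRICTION = 1.0
DEFAULT_TEMPERATURE = 0.92
#: desk-scale default; the multi-billion-step regime is a configuration
#: value, not a default
DEFAULT_STEPS = 5_000_000
DEFAULT_STRIDE = 1_000


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulationParams:
    timestep: float = DEFAULT_TIMESTEP
    friction: float = DEFAULT_FRICTION
    temperature: float = DEFAULT_TEMPERATURE
    n_steps: int = DEFAULT_STEPS
    stride: int = DEFAULT_STRIDE
    seed: int = 0

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if not (0 <= int(self.seed) < 2 ** 31):
            raise ValueError("seed must fit in 31 bits")


@dataclass
class Trajectory:
    frames: np.ndarray        # (n_frames, n_beads, 3)
    energies: np.ndarray      # (n_frames,) total potential energy
    params: SimulationParams
    seed: int
    kinetic: np.ndarray = None  # (n_frames,) kinetic energy

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def to_dict(self) -> dict:
        return {"params": asdict(self.params), "seed": self.seed,
                "n_frames": self.n_frames}


def langevin_run(
    ff: ForceField,
    start_coords: np.ndarray,
    params: SimulationParams,
    mobile: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the potential and record frames at the stride.

    Frame 0 is the starting configuration; ``floor(n_steps / stride)``
    further frames follow.  ``mobile`` optionally freezes beads (anchors);
    default all beads move.  Initial velocities are Maxwell–Boltzmann at
    the run temperature, drawn from the same seeded stream as the
    thermostat noise.
    """
    coords = np.ascontiguousarray(start_coords, dtype=float)
    if coords.shape != (ff.n_beads, 3):
        raise ForceFieldError("start coordinates do not match the forcefield")
    if not np.all(np.isfinite(coords)):
        raise ForceFieldError("non-finite start coordinates")
    if mobile is None:
        mobile = np.ones(ff.n_beads, dtype=np.bool_)
    mobile = np.ascontiguousarray(mobile, dtype=np.bool_)

    rng = np.random.default_rng(params.seed)
    if params.temperature > 0:
        vel = rng.normal(0.0, np.sqrt(params.temperature), coords.shape)
        vel[~mobile] = 0.0
    else:
        vel = np.zeros_like(coords)
    kernel_seed = int(rng.integers(0, 2 ** 31 - 1))

    n_frames = params.n_steps // params.stride + 1
    frames = np.empty((n_frames, ff.n_beads, 3), dtype=float)
    energies = np.empty(n_frames, dtype=float)
    kinetic = np.empty(n_frames, dtype=float)

    status, step = _kernels.langevin_run_kernel(
        coords, vel,
        ff.bond_idx, ff.bond_r0, ff.bond_k,
        ff.angle_idx, ff.angle_th0, ff.angle_k,
        ff.dihedral_idx, ff.dihedral_phi0, ff.dihedral_k,
        ff.contact_idx, ff.contact_r0, ff.contact_eps, ff.sigma, ff.r_excluded,
        ff.ev_pairs,
        mobile,
        int(params.n_steps), float(params.timestep), float(params.friction),
        float(params.temperature), int(params.stride), kernel_seed,
        frames, energies, kinetic,
    )
    if status != 0:
        raise SimulationError(f"energy diverged at step {step}")
    return Trajectory(frames, energies, params, params.seed, kinetic)
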
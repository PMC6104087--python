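# dlptether

Coarse-grained structure-based simulation of **tethered GTPase-domain
dimerisation** in dynamin-like protein (DLP) complexes, plus the
structural-geometry utilities (buried surface area, superposition RMSD,
hinge rotation, tether reach) that support the mechanistic analysis.

## The problem

Bacterial DLP heterotetramers place two GTPase (G-) domains on a rigid
central dimer, each held by a short (~9-residue) random-coil linker.
Assembly-stimulated GTP hydrolysis requires the two G-domains to dimerise
head-to-head across their nucleotide-binding pockets — but can the tether
reach, and how strongly must the interface attract for the dimerised
state to be populated?  `dlptether` answers this with a Cα
structure-based (Gō-type) model: one bead per residue, harmonic
bonds/angles, cosine dihedrals, Gaussian attractive wells at the native
contact distances,

V_contact(r) = ε [ (1 + (r_ex/r)¹²)(1 − e^{−(r−r₀)²/2σ²}) − 1 ],

and an added inter-domain interface contact set whose depth is a tunable
fraction of the native ε.  Langevin dynamics in reduced units (dt
0.0005, friction 1, T* = 0.92) samples reversible dimerisation; the
fraction of frames with most interface contacts formed (Q_int ≥ 0.5) is
the dimer occupancy, reported with a block-bootstrap CI, and
−T*·ln P over the reaction coordinates gives the free-energy surface.

The package is organised as a library with a thin CLI
(`dlptether prepare|contacts|dock|simulate|analyze|geometry|synth|pipeline`):
structure I/O and Cα coarse-graining, shadow/cutoff native-contact maps,
template-based heterodimer docking, the forcefield and integrator
(numba kernels), trajectory analysis, geometry utilities, and a
synthetic-system generator that reproduces the tethered topology at
desk scale (~80 beads) so the whole pipeline runs in minutes.

## Worked example

```python
from dlptether import RunConfig, run_tether_pipeline

cfg = RunConfig(interface_strength=0.5, seed=11,
                simulation={"n_steps": 5_000_000, "stride": 1000})
res = run_tether_pipeline(cfg, "out/")
occ = res["occupancy_q"]
print(f"dimer occupancy {occ.fraction:.3f} "
      f"[{occ.ci_low:.3f}, {occ.ci_high:.3f}]")
print(f"docked marker distance {res['d_series'].values.min():.1f} Å at closest")
```

prints, for this seed:

```
dimer occupancy 0.052 [0.000, 0.157]
docked marker distance 4.8 Å at closest
```

meaning that at half-native interface strength this *desk-scale* system
visits the dimerised state transiently (the CI quantifies the sampling
uncertainty of an autocorrelated trajectory), and the marker groups do
reach contact range — the tether is long enough.  Raising the strength
factor to 2 locks the dimer (occupancy ≈ 1), and
`dlptether.analysis.tune_interface_strength` bisects the factor to any
target occupancy, e.g. 50%.  `out/` contains the trajectory, the
tab-separated coordinate series, contact lists, topology, and a
`manifest.json` recording seeds, parameters and checksums; re-running
the persisted config reproduces every series byte-for-byte.

The geometry side works on any structure:

```bash
dlptether geometry bsa complex.pdb --part-a A --part-b B        # buried area, both conventions
dlptether geometry reach --segments rigid:200,linker:9,rigid:200
```

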
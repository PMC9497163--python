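#!/usr/bin/env python
"""Generate the synthetic study inputs with known ground truth.

Writes TIFF images plus machine-readable truth side-files under
results/simulated/: ring textures for the two culture scenarios (E0: weak
bias, EA: strong bias) and an isotropic control, one junction network, one
bead pair over a contractile ring, one calcium trace, and grouped TEER
records.  Downstream analysis scripts read only the images/records, never
the truth files.
"""

import json
import sys
from pathlib import Path

import numpy as np

from bbbq import core_io, synthetic, tfm

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/simulated")
OUT.mkdir(parents=True, exist_ok=True)
PS = 0.645

# --- chiral ring textures -------------------------------------------------
geo = core_io.PatternGeometry("ring", center=(90.0, 90.0), diameter=160.0,
                              band_width=45.0)
scenarios = {"E0": 5.0, "EA": 15.0, "control": None}
for name, bias in scenarios.items():
    kappa = 0.0 if bias is None else 6.0
    truth = synthetic.ChiralityTruth(bias or 0.0, kappa, geo)
    stack, t2 = synthetic.gen_ring_texture(truth, (280, 280),
                                           seed=SEED, pixel_size=PS)
    core_io.save_stack(stack, OUT / f"ring_{name}.tif")
    (OUT / f"ring_{name}.truth.json").write_text(json.dumps({
        "bias_deg": truth.bias_deg, "kappa": kappa,
        "center_um": geo.center, "diameter_um": geo.diameter,
        "band_width_um": geo.band_width}, indent=1))

# --- junction network -----------------------------------------------------
stack, truths = synthetic.gen_junction_network(12, 2.5, 3.0, (256, 256),
                                               seed=SEED, pixel_size=PS)
core_io.save_stack(stack, OUT / "junctions.tif")
(OUT / "junctions.truth.json").write_text(json.dumps(
    [{"arc_um": t["arc_um"], "chord_um": t["chord_um"], "ratio": t["ratio"]}
     for t in truths], indent=1))

# --- bead pair over a contractile ring ------------------------------------
n = 192
half = n * PS / 2
ring = core_io.PatternGeometry("ring", center=(half, half),
                               diameter=0.6 * n * PS,
                               band_width=0.25 * n * PS)
gel = tfm.GelProperties(5000.0, 0.45)
tx, ty = synthetic.make_ring_traction(ring, (n, n), PS, magnitude_pa=100.0,
                                      tangential_frac=-0.1,
                                      profile_sigma_um=ring.band_width / 2.5)
ref, deformed, truth = synthetic.gen_bead_pair(tx, ty, gel, n_beads=3000,
                                               image_shape=(n, n),
                                               seed=SEED, pixel_size=PS)
core_io.save_stack(ref, OUT / "beads_ref.tif")
core_io.save_stack(deformed, OUT / "beads_def.tif")
(OUT / "beads.truth.json").write_text(json.dumps({
    "magnitude_pa": 100.0, "tangential_frac": -0.1,
    "youngs_modulus_pa": gel.youngs_modulus_pa,
    "poisson_ratio": gel.poisson_ratio,
    "net_force": truth.net_force}, indent=1))

# --- calcium trace --------------------------------------------------------
sparks = [synthetic.SparkTruth(onset_s=60.0 + k * 120.0, amplitude_dFF0=2.0,
                               time_to_peak_s=9.0, decay_tau_s=30.0,
                               baseline_F=100.0, noise_sd=10.0)
          for k in range(8)]
trace, _ = synthetic.gen_calcium_trace(sparks, n_frames=400,
                                       frame_interval=3.0, seed=SEED)
np.savetxt(OUT / "calcium_trace.csv",
           np.column_stack([trace.times(), trace.F]),
           delimiter=",", header="time_s,F", comments="")
(OUT / "calcium.truth.json").write_text(json.dumps(
    [{"onset_s": s.onset_s, "amplitude_dFF0": s.amplitude_dFF0,
      "time_to_peak_s": s.time_to_peak_s, "decay_tau_s": s.decay_tau_s}
     for s in sparks], indent=1))

# --- barrier records ------------------------------------------------------
records = synthetic.gen_barrier_records(
    {"control": 150.0, "E0": 165.0, "EA": 185.0},
    {"control": 5.0, "E0": 5.0, "EA": 5.0}, 8,
    area_cm2=4.5, seed=SEED, r_m_ohm=120.0)
core_io.write_results(records, OUT / "teer_records.csv")

print(f"simulated inputs written to {OUT} (seed {SEED})")
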
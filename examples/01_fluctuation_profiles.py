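"""Per-loop RMSF profiles on the synthetic TCR-like demo receptor.

Generates the A6-like toy ensemble (planted: a highly mobile CDR3β-like loop,
a rigid correlated CDR1α/CDR2α pair), superposes it, and prints the maximum
Cα RMSF per CDR loop.  The printed ranking should place CDR3b far above the
germline loops — the planted mobility contrast recovered by the analysis.
"""

from pathlib import Path

import yaml

from loopdyn import (SelectionMask, generate_demo_data, read_ensemble,
                     resolve_loops, rmsf, superpose)

out = Path("scratch_example_data")
paths = generate_demo_data(seed=11, out_dir=out, receptor="A6", n_frames=500)
ensemble = read_ensemble(paths["ensemble"])
mask = SelectionMask.alpha_carbons(ensemble.topology)
ensemble = superpose(ensemble, mask, 0)

profile = rmsf(ensemble, mask)
by_residue = dict(zip([r[:2] for r in profile.references], profile.rmsf))

config = yaml.safe_load(open(paths["config"]))
loops = resolve_loops(ensemble.topology,
                      {k: tuple(v) for k, v in config["loops"].items()})
print(f"{'loop':8s} {'length':>6s} {'max RMSF (A)':>13s}")
for loop in sorted(loops, key=lambda l: l.name):
    peak = max(by_residue[(loop.chain_id, int(r))] for r in loop.res_ids)
    print(f"{loop.name:8s} {len(loop):6d} {peak:13.2f}")
print("\nHighest value = most mobile loop; the planted contrast makes "
      "CDR3b dominate.")
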
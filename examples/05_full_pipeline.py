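"""Run the packaged demo analysis end-to-end.

Writes a synthetic fixture set (four predictor rasters, three species'
occurrence files echoing field-study sample sizes 45/200/110), then
executes the whole pipeline: clean -> thin -> terrain -> VIF -> fit five
algorithms per species -> evaluate -> ensemble -> binarize -> overlap.
Outputs land in ./scratch/demo/run; rerunning with the same seed
reproduces them bit-for-bit.
"""

import json
from pathlib import Path

from sdmniche import make_demo, run_pipeline

config = make_demo("two-prey-demo", "scratch/demo", rng_seed=1234)
manifest = run_pipeline(config)

print("record bookkeeping per species (raw -> deduplicated -> thinned):")
for sp in config.occurrences:
    c = manifest.counts
    print(f"  {sp:13s} {c[sp + '_raw']:>4d} -> {c[sp + '_deduplicated']:>4d} "
          f"-> {c[sp + '_thinned']:>4d}")

overlap = json.loads((Path(config.out_dir) / "overlap.json").read_text())
d = overlap["schoener_d"]
print("Schoener's D, predator vs prey:")
for prey in ("prey_similar", "prey_distant"):
    print(f"  {prey:13s} D = {d[prey]['predator']:.3f}")
# The prey species built with a niche close to the predator's shows much
# higher overlap than the one with a distant niche — the pattern the
# method is designed to quantify.
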
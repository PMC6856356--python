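# woundtrack

Quantitative analysis of chemokine-receptor internalization and neutrophil
migration behavior at wounds, for researchers doing live imaging of
inflammatory responses (e.g. zebrafish larval wound models).

When neutrophils respond to tissue damage, the fate of their chemokine
receptors shapes the response: a receptor that stays on the plasma membrane
keeps driving motility, while one that is internalized into vesicles stops
signaling. `woundtrack` implements two complementary measurement layers:

**Receptor internalization by texture contrast.** A membrane-resident
receptor-GFP gives a smooth rim of fluorescence; an internalized receptor
gives a punctate, vesicular pattern. Per segmented cell the package computes
the gray-level co-occurrence matrix (GLCM) contrast

&nbsp;&nbsp;&nbsp;&nbsp; C = Σ<sub>i,j</sub> |i − j|² p(i, j)

over intensities quantized to N gray levels inside the surface mask, where
p(i, j) is the joint frequency of levels i, j at a fixed pixel offset. C is
low for smooth membranous patterns and high for punctate ones, and is
invariant to detector gain/offset. Contrast can be normalized to reference
cells (non-mobilized cells in the hematopoietic tissue) or to the movie
maximum, and profiled against the distance to the wound margin to map
spatial ligand gradients. Ratiometric membrane-level and chemokine-uptake
scores are also provided.

**Migration behavior against the occupied wound area (owa).** Cell tracks
(t, x, y) are classified against the polygon covered by the neutrophil
cluster: *forward* segments run up to first owa entry, *reverse* segments
from the last in-owa time point onward. Per step the package derives speed
v<sub>t</sub> (µm/min), distance to the nearest owa-perimeter point
d<sub>t</sub>, and the approach-angle cosine cos θ<sub>t</sub>; per track,
straightness S = net displacement / path length within a 50 µm zone; per
cohort, net reverse traffic = (# reverse tracks)/(# forward owa-intersecting
tracks), plus binned speed–distance and speed–orientation profiles and
cluster/recruitment statistics.

A synthetic-scene generator (fluorescence phantoms with known vesicular
fraction; biased persistent-random-walk cohorts with ground-truth
forward/reverse labels) makes every stage testable without microscopy data.

## Worked example

```python
import numpy as np
from shapely.geometry import Polygon
from woundtrack import synthetic as syn
from woundtrack import internalization as itl
from woundtrack import trajectories as traj

# score receptor distribution phenotypes at matched total fluorescence
membrane = syn.ScenePhantomParams(vesicular_fraction=0.0, rng_seed=0)
vesicular = syn.ScenePhantomParams(vesicular_fraction=1.0, rng_seed=0)
img_m, surface, _ = syn.render_cell_image(membrane)
img_v, _, _ = syn.render_cell_image(vesicular)
print(f"contrast (membranous): {itl.cell_contrast(img_m, surface):.3f}")
print(f"contrast (internalized): {itl.cell_contrast(img_v, surface):.3f}")

# simulate a wound-recruitment cohort and measure reverse traffic
owa = Polygon([(40, 120), (100, 120), (100, 180), (40, 180)])
walkers = syn.WalkerParams(n_tracks=200, bias_strength=8.0, bias_range=1000.0,
                           p_reverse=0.3, rng_seed=0)
tracks = [traj.Track(t.track_id, t.t, t.x, t.y)
          for t in syn.simulate_tracks(walkers, owa)]
cls = [traj.classify_track(t, owa) for t in tracks]
summary = traj.cohort_summary(cls, [traj.straightness(t, owa) for t in tracks])
print(f"forward-intersecting tracks: {summary['n_forward_intersecting']}")
print(f"reverse segments: {summary['n_reverse_segments']}")
print(f"net reverse traffic: {summary['net_reverse_traffic']:.3f}")
```

prints

```
contrast (membranous): 0.767
contrast (internalized): 2.831
forward-intersecting tracks: 200
reverse segments: 58
net reverse traffic: 0.290
```

The internalized phantom scores ~4× the contrast of the membranous one at
identical integrated fluorescence, and the measured net reverse traffic
(0.290) recovers the simulated 30% reversal probability.

## Command line

End-to-end runs are driven by a YAML config with a mandatory seed:

```
woundtrack all --config run.yaml --outdir runs/demo
```

Subcommands `simulate-scene`, `simulate-tracks`, `segment`,
`internalization`, `trajectories` and `clusters` run individual stages; a
manifest JSON with a config hash makes each run self-describing, and reruns
with the same config and seed are byte-identical.

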
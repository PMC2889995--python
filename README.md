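# granuloc

Object-based co-localization and co-trafficking quantification for
multichannel confocal fluorescence stacks.

Neuronal mRNAs travel in RNA granules, and asking whether a transcript and
a protein ride in the *same* granule comes down to image quantification:
detect discrete fluorescent puncta in each channel, decide which puncta
from different channels occupy the same site, and report what fraction of
each population co-localizes. `granuloc` implements that chain for 2–3
channel z-stacks (FISH + immunofluorescence) and time-lapse series:

- **Puncta detection** — a punctum is a connected region of voxels with
  intensity strictly above the *local* background mean + 2·SD (moving-window
  statistics, per optical section).
- **Object-based co-localization** — puncta `A`, `B` from two channels
  co-localize when `|A ∩ B| / min(|A|,|B|) > 0.30`; directional percent
  co-localization is `100 × (reference puncta with ≥1 partner) / n_ref`.
  Pairwise and triple counts are both computed.
- **Seven-color segmentation** — each pixel of an RGB composite is assigned
  to the nearest of seven color-cube corner vectors (red, green, blue,
  yellow, magenta, cyan, white) by minimal angular deviation, yielding seven
  pseudo-channel masks (single targets, pairwise overlaps, triple overlap).
- **Projection** — maximum-intensity projection and y-axis rotation series
  with correct anisotropy scaling: slice spacing in pixels =
  `pixel_count × z_interval / field_size` (512 × 0.5 / 90 = 2.84 px).
- **Trafficking** — nearest-centroid track linking across time-lapse
  frames, travel distance in µm, and co-trafficking fractions.
- **Synthetic data** — a simulator that renders confocal-like stacks with
  known puncta positions and planted co-localization fractions, so the whole
  chain is testable without microscopy data.

See `docs/methods.md` for the models, parameter defaults, and limitations.

## Worked example

Simulate a 3-channel stack with 15% planted pairwise co-localization,
detect puncta, and score co-localization:

```python
import granuloc as g

params = g.SimParams(shape=(8, 256, 256), n_channels=3, n_puncta=200,
                     coloc_fraction=0.15, seed=2)
stack, truth = g.simulate_stack(params)

puncta = {c: g.detect_puncta_channel(stack.channels[c], c)
          for c in stack.channel_names}
res = g.percent_colocalization(puncta["ch0"], puncta["ch1"])
print(f"{res.n_coloc_events}/{res.n_ref_events} = {res.percent:.1f}%  "
      f"(planted {g.expected_coloc(truth)[('ch0','ch1')]:.1f}%)")
```

prints

```
30/198 = 15.2%  (planted 15.0%)
```

200 puncta were planted per channel, 30 of them paired across ch0/ch1;
detection found 198 of the 200 reference puncta, all 30 pairs overlapped
above the 30% rule, and the directional percentage (events over the
reference population) recovers the planted 15% within rounding. The same
objects feed `g.triple_colocalization`, and `g.rotation_series(stack)`
builds a 3D turntable rendering with the 2.84-px slice spacing taken from
the stack geometry.

The shell interface mirrors this: `granuloc simulate --out simdir --seed 2`
writes the stack and its ground-truth table, `granuloc run config.yaml`
executes the full pipeline from a YAML config (inputs, geometry, detection
and overlap parameters) and writes the co-localization report, puncta
tables, pseudo-channel masks and projections, and `granuloc segment`
runs seven-color segmentation alone. Input TIFFs are multipage grayscale,
channels interleaved within each slice; voxel geometry comes from the
config, not from TIFF metadata.

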
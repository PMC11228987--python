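# memgate

Protein–membrane interface analysis for molecular-dynamics
trajectories of peripheral lipid-transfer domains.

When a START-family lipid-transfer domain (the CERT START domain is
the motivating case) docks onto a bilayer, a characteristic sequence
unfolds: the domain binds and tilts, the two loops flanking the cavity
entrance (Ω1/Ω4) separate — the *gate* opens — exposed tryptophans
engage choline head groups, hydrogen bonds form with lipid glycerols,
and lipid tails *snorkel* upward and insert into the hydrophobic
cavity. `memgate` turns those observations into reproducible,
threshold-explicit measurements:

* **persistent interaction inventories** — hydrophobic contacts
  (apolar pairs ≤ 3 Å), hydrogen bonds (H···A ≤ 2.4 Å and
  D–H–A ≥ 130°) and cation–π interactions (all six ring atoms < 7 Å
  from a choline N), each requiring ≥ 2 consecutive frames and
  presence in **all** replicas for the consensus inventory;
* **membrane-referenced descriptors** — binding-event detection,
  per-residue insertion depth of Cβ (Cα for Gly) against the
  time-averaged phosphorus plane, helix tilt versus the membrane
  normal, and weighted density profiles along z;
* **lipid conformational classification** — tail tilt from the
  C2 → C218/C316 vector on the full [0°, 180°] range (≥ 150° bilayer,
  ≤ 45° cavity-inserted), snorkeling (terminal carbon above 5 Å below
  the phosphorus plane for > 1% of frames), and counts of perturbed
  lipids under the gate footprint with an opposite-leaflet baseline;
* **gate-state quantification** — the W473–P564 / S476–W562 analogue
  distance series, kernel density estimates of the open/closed state
  distribution, and threshold segmentation with open-fraction
  reporting.

A fully scripted **synthetic-trajectory generator** plants binding,
gate-opening, hydrogen-bond, contact, snorkeling and tail-insertion
events with a machine-readable ground-truth log, so every detector is
validated frame-exactly without downloading any trajectory data.

## Worked example

```python
from memgate import (RunConfig, run_pipeline, validate_against_eventlog)

config = RunConfig(seed=7, outdir="demo_out")   # built-in synthetic scenario
bundle = run_pipeline(config)

print("binding frame:", bundle["binding_frames"][0])
print("tilt: %.1f +/- %.1f deg" % (bundle["tilt"]["mean"],
                                   bundle["tilt"]["sd"]))
print("gate open fraction: %.3f" % bundle["open_fraction"])
print("consensus interactions:", len(bundle["consensus"].table))
print(validate_against_eventlog(bundle, bundle["event_log"]).empty)
```

prints

```
binding frame: 49
tilt: 40.0 +/- 0.0 deg
gate open fraction: 0.305
consensus interactions: 7
True
```

The scenario plants binding completing near frame 49 of 200 (a 2 μs
toy trajectory at 10 ns/frame), holds the rigid helix at 40° from the
membrane normal, opens the gate for 61 frames (open fraction
61/200 = 0.305), and the consensus inventory picks up the planted
hydrogen bond and hydrophobic contact plus the cation–π and packing
interactions that follow from the bound geometry. The final `True` is
the ground-truth check: the pipeline recovered every planted event
frame-exactly.

The same pipeline runs from the shell:

```
memgate simulate --seed 7 --outdir scenario/       # topology + frames + event log
memgate analyze  --config run.yaml                 # CSV + JSON reports
memgate validate --config run.yaml                 # compare vs. event log
```

Real trajectories are analysed by pointing `RunConfig.inputs` (or the
YAML `inputs:` block) at a PDB/PSF topology and DCD/XTC (or
plain-text) trajectory files; all thresholds live in the config and
default to the criteria above.

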
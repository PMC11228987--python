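# Methods

## What the package computes

`memgate` analyses molecular-dynamics trajectories of a peripheral
lipid-transfer domain (the START domain of CERT is the motivating
system) engaging a lipid bilayer. The analysis chain is:

1. **Binding detection** — the first frame from which the minimum
   protein–bilayer heavy-atom distance stays at or below a contact
   cutoff for a sustained dwell. All subsequent "bound-form" analyses
   run from that frame to the end of the trajectory.
2. **Phosphorus-plane reference** — the per-frame mean z of the
   protein-proximal leaflet's phosphorus atoms and its time average
   over the bound window. Depth and snorkeling are measured against
   this plane.
3. **Insertion depth** — per residue, the signed z-distance of the Cβ
   (Cα for glycine) from the averaged plane: positive above the
   phosphates, negative inserted below them.
4. **Helix tilt** — the angle between the membrane normal and the
   C-terminal helix axis defined by two Cα anchors (the A565→T591
   analogues), folded to [0°, 90°].
5. **Density profiles** — weighted number density along z over a
   trailing window (default the last 500 ns), with electron-count
   (atomic number), mass, or unit weighting. Atomic-number weighting is
   the default stand-in for a full electron-density calculation; it is
   reproducible from the topology alone.
6. **Interaction inventories** — three detectors sharing one
   persistence rule (criterion satisfied in ≥ 2 consecutive saved
   frames; one bad frame terminates a run):
   * hydrophobic contact: two unbound apolar candidate atoms within
     3 Å. "Unbound" excludes covalent (1–2), angle (1–3) and
     intra-residue pairs. The default candidate set is carbons with no
     N/O/S/P neighbour plus Cys/Met sulfur, overridable per atom.
   * hydrogen bond: H···A ≤ 2.4 Å **and** D–H–A ≥ 130°
     simultaneously.
   * cation–π: *every* atom of a Trp/Phe/Tyr six-ring strictly within
     7 Å of a choline nitrogen.
   Events are aggregated to residue–partner level (one qualifying atom
   pair suffices); the consensus inventory keeps only partner pairs
   detected in **all** replicas, with per-replica occupancies reported
   alongside. Occupancy statistics are computed per replica first and
   consensus applied after (the alternative order is available by
   filtering per-replica tables before aggregation).
7. **Lipid conformations** — per tail, the angle between the glycerol
   C2 → terminal-carbon vector (CHARMM C218/C316 naming; terminal =
   highest-numbered chain carbon, overridable) and the membrane
   normal, **unfolded** to [0°, 180°] because ≥ 150° (tail down in the
   bilayer, upper leaflet) and ≤ 45° (tail swung up into the protein
   cavity) are distinct states. Snorkeling: the terminal carbon above
   5 Å below the phosphorus plane for strictly more than 1% of
   analysed frames; mirrored for the lower leaflet against that
   leaflet's own plane. The lipids-under-the-gate counter reports, per
   frame, deviant lipids (snorkeling or inserted) whose phosphorus is
   within a footprint radius (default 15 Å) of the gate-residue
   centroid, plus the same predicate applied to the whole opposite
   leaflet as a baseline.
8. **Gate state** — two diagnostic distances (W473–P564 and S476–W562
   analogues; default closest-heavy-atom, robust to side-chain flips,
   with Cα–Cα and named-atom modes), a Gaussian KDE of the distance
   distribution (Scott's rule bandwidth, renormalized on its grid),
   and a two-state segmentation at a threshold that defaults to the
   midpoint of the two KDE modes, with a minimum-dwell merge rule.

## The synthetic-data generator

Real microsecond trajectories are deposited externally and are not
needed here: the generator builds a toy system in which every detector
has exact ground truth.

* **Bilayer**: two leaflets of simplified phosphatidylcholine-like
  lipids on an 8 Å grid, phosphorus planes at ±20 Å. Each lipid has a
  choline nitrogen with three methyls, a phosphorus, a three-carbon
  glycerol with the C2 carbon, one ester oxygen (hydrogen-bond
  acceptor) and two eight-carbon tails named `C22…C29` / `C32…C39`, so
  the same name-parsing rules accept real CHARMM lipids (`C218`,
  `C316`).
* **Protein**: a rigid pseudo-domain whose residues include analogues
  of the gate residues W473/S476 (loop 1) and W562/P564 (loop 4), each
  tryptophan with an explicit aromatic six-ring, a serine hydroxyl
  donor, and a helix from A565 to T591 laid at 40° from the normal.
  The closed-gate W473–P564 Cα distance is exactly 7 Å. All
  inter-residue apolar pairs are kept > 3.2 Å apart so an event-free
  scenario produces no hydrophobic contacts. In the bound pose the
  minimum heavy-atom gap to the bilayer is 3.5 Å (found by bisection on
  a vertical offset); without a scheduled binding event the protein is
  held 15 Å higher, in solution.
* **Events** are realized geometrically inside inclusive frame
  windows: binding as a linear 15 Å descent; gate opening as a lateral
  loop-1 displacement taking the diagnostic distance from 7 to 15 Å;
  hydrogen bonds by placing a lipid ester oxygen at 1.9 Å from the
  serine hydroxyl hydrogen at a 165° donor–hydrogen–acceptor angle;
  hydrophobic contacts by placing a mid-chain tail carbon 2.5 Å from
  an exposed apolar helix carbon; snorkeling by raising a terminal
  carbon to 3 Å below the phosphorus plane; tail insertion by laying
  the sn-2 chain along a 30° (inserted) or 160° (bilayer) vector.
  `*_off` variants hold the interaction from frame 0 and break it at
  the window start. The event log records both the scheduled window and
  the frame range over which the state actually holds.
* **Noise** is isotropic Gaussian positional jitter (default σ = 0,
  σ = 0.2 Å in the noisy validation condition), drawn from
  `numpy.random.default_rng` (PCG64), so a seed reproduces scenarios
  bit-for-bit across platforms; replicas share the scripted geometry
  and differ only in their noise streams (seed + replica index).
  Planted hydrogen-bond/contact partners are re-placed relative to the
  *noised* anchor positions and receive only attenuated residual
  jitter (0.25 σ): a formed interaction constrains the partner atom, and
  uncorrelated jitter on both sides would make a boundary criterion
  flicker in a way no bonded geometry does. The hydrophobic plant at
  2.5 Å (versus the 3 Å cutoff) likewise leaves ≥ 5 standard deviations
  of pair-distance jitter at σ = 0.2 Å.

What the generator does **not** emulate: any force field or
thermodynamics, conformational flexibility beyond the scripted moves,
realistic lipid packing or composition, water, or correlated thermal
motion. Passing tests therefore demonstrate that the *detectors and
bookkeeping* are correct at the printed criteria and tolerances — not
that the criteria themselves are optimal for real membranes.

## Numerical choices

* Units: Å, ns, degrees, Da. Frames are 0-based; windows inclusive.
* Minimum image applied in x/y only; slab systems are assumed aligned
  with the membrane normal on z and not wrapped across z, which avoids
  spurious cross-leaflet contacts. Triclinic boxes are out of scope.
* Inclusive thresholds (≤ 3 Å, ≤ 2.4 Å, ≥ 130°) are compared with a
  1e-9 epsilon so geometries constructed exactly at a printed boundary
  are accepted regardless of the floating-point representation of the
  constant; strict criteria (< 7 Å; > 1% of frames) use no epsilon,
  and the snorkeling fraction is compared on frame counts
  (`hits > threshold × n_frames`).
* Leaflet assignment is fixed from the first analysis frame (above or
  below the mean phosphorus z); flip-flop is not tracked — rare on
  these timescales.
* RMSD uses uniform weights with an optimal (Kabsch) superposition via
  `scipy.spatial.transform.Rotation.align_vectors`; a no-refit mode
  exists for pre-aligned trajectories, where a single-atom displacement
  obeys the closed form √(d²/N) exactly. Either atom selection (with
  or without a mobile terminus) is expressible through the selection
  language.
* The protein tilt is folded to [0°, 90°]; lipid tail tilt is not
  (see above).
* Segmentation merges sub-dwell intervals shortest-first (ties:
  leftmost) into their neighbours, so intervals always tile the
  trajectory exactly.
* KDE bandwidth follows Scott's rule unless overridden; the density is
  evaluated on a regular grid padded by three bandwidths and
  renormalized so the grid quadrature integrates to one.
* The binding criterion (not printed in the source analysis) defaults
  to minimum heavy-atom distance ≤ 4 Å sustained ≥ 10 ns, both
  configurable.
* Bond information prefers explicit topology (PSF) bonds; otherwise a
  covalent-radius heuristic (rᵢ + rⱼ + 0.4 Å) over intra-residue and
  consecutive-residue pairs.
* Depth defaults to the plane averaged over the whole bound window; a
  per-frame-plane mode is available.

## Problem sizes

The default synthetic condition is 16 lipids per leaflet (≈ 840
atoms), 200 frames at 10 ns spacing (a 2 μs trajectory), two replicas
— large enough that every detector, the consensus rule and the
windowed series are exercised end-to-end, and small enough that the
whole validation suite replays in minutes. Oracle-equivalence checks
use 20 random systems of 40–80 atoms and 15–60 frames against pure
Python brute-force detectors.

## Known limitations

* The published candidate-atom table for hydrophobic contacts is not
  redistributed; the element/connectivity heuristic stands in and can
  be overridden with an explicit atom list when the table is at hand.
* Electron density is approximated by atomic-number weighting, not a
  form-factor calculation.
* No water-mediated hydrogen bonds, π–π stacking or dedicated
  salt-bridge detector (charged-group hydrogen bonds are reported by
  the hydrogen-bond machinery).
* The "under the gate" footprint is a configurable radius around the
  gate-residue centroid; the underlying observation does not define a
  quantitative footprint.
* Area-per-lipid, order parameters, curvature, flip-flop kinetics and
  free-energy estimates are out of scope.
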
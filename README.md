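# protofil

Geometry, interface-contact and morphometric analysis for two-subunit
(dimer) MD trajectories of filament-forming proteins such as the bacterial
tubulin homologue FtsZ.

FtsZ polymerizes into protofilaments that assemble the cytokinetic Z ring.
Point mutations can change the preferred *inter-subunit twist* of the
filament; a twisted filament wraps the membrane as a helix instead of a
ring, with drastic consequences for where the cell builds new wall.
`protofil` provides the quantitative pipeline for asking such questions of
a dimer trajectory:

* **Inter-subunit twist and bend.** For each frame, the twist is the signed
  angle (right-hand rule about the inter-centroid axis **u**) between the
  projections of the two subunits' longest principal axes e₁ onto the plane
  ⊥ **u**, referenced to the first frame; the bend is the swing component of
  the swing–twist decomposition of the relative subunit rotation about
  **u**. Axis signs follow temporal continuity, and series are unwrapped so
  no step exceeds 180°.
* **Filament extrapolation.** The rigid map T superposing subunit A onto
  subunit B (Kabsch, Cα atoms by default) is applied repeatedly: subunit k
  of the model is Tᵏ(subunit 0). The screw decomposition of T (rotation θ
  about a unique axis plus rise d along it) gives the helical parameters:
  twist/subunit θ, rise/subunit d, subunits/turn 360°/|θ|, helix radius.
* **Interface contacts.** Residue pairs spanning the two subunits whose
  closest heavy atoms lie within 5 Å; per-pair occupancy in 12.5-ns blocks;
  a three-rule temporal classifier separating pairs specific to the
  nontwisted state, pairs general to twisted states, and variant-specific
  pairs; center-of-mass distance traces for named pairs (e.g. the
  Arg67–Asp97 cross-interface salt bridge).
* **Morphometrics.** Cell aspect ratios (length/width, or the
  moment-equivalent-ellipse ratio of a pixel mask) and polymer-length
  samples, compared with the Mann–Whitney U test — exact by full
  enumeration for n+m ≤ 16 without ties, normal approximation with
  continuity and tie correction otherwise.
* **Synthetic trajectories with planted truth.** Since real multi-hundred-ns
  trajectories are rarely redistributable, the `synthetic` module generates
  dimer trajectories with a prescribed twist profile (constant, linear or
  logistic θ(t)), fixed rise, per-atom Gaussian noise and scheduled
  interface contacts, plus two-condition aspect-ratio samples — every
  estimator in the package is validated against these planted parameters.

## Worked example

`examples/twist_series.py` simulates the "variant-like" preset — a 300-ns,
240-frame dimer trajectory whose planted logistic twist reaches 20° with a
midpoint at 25 ns, under 0.5 Å per-atom coordinate noise — and recovers the
twist series from the coordinates alone:

```
frames: 240, span: 300 ns
twist at 50 ns:   17.48 deg (planted 16.97)
final twist:      18.51 deg (planted 18.48)
recovery RMS error over the series: 0.50 deg
```

The dimer is already twisted by >15° within the first 50 ns, and the
estimator tracks the planted profile to half a degree through the noise.
The other examples cover filament building (`build_filament.py`: a
25.7°/subunit generator closes one turn in 14.01 subunits), contact
classification (`contact_classification.py`: the variant-specific group is
non-empty only against the variant-like run), the salt-bridge break time
(`salt_bridge_trace.py`) and two-condition morphometrics
(`cell_morphometrics.py`).

A thin CLI wraps the same functions:

```sh
protofil simulate --preset variant-like --seed 1 --out var.pdb --truth truth.csv
protofil simulate --preset wt-like --seed 2 --out wt.pdb
protofil classify-contacts --wt wt.pdb --variant var.pdb --out classes.csv
protofil build-filament --in dimer.pdb --n 14 --out filament.pdb --report helix.csv
protofil morphometrics --in cells.csv --group-col condition
```

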
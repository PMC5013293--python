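"""Classify cross-subunit contacts between a WT-like and a variant-like run.

Simulates both presets, block-averages 5 A contact occupancy in 12.5-ns
blocks, and applies the three temporal rules: early-WT-only pairs mark the
nontwisted interface, pairs shared by twisted states arrive late in WT, and
variant-only pairs mark the mutant-specific interface.
"""

import protofil as pf

occ = {}
for name, seed in (("wt-like", 1), ("variant-like", 2)):
    traj, _ = pf.simulate_dimer_trajectory(pf.preset_spec(name, seed=seed))
    occ[name] = pf.occupancy_matrix(traj, block_ns=12.5, cutoff_A=5.0)
    print(f"{name}: {len(occ[name].pairs)} contact pair(s), {occ[name].n_blocks} blocks")

cls = pf.classify_contacts(occ["wt-like"], occ["variant-like"])
for (ra, rb), label in sorted(cls.labels.items()):
    names = cls.resnames[(ra, rb)]
    print(f"  {names[0]}{ra} - {names[1]}{rb}: {label}")
print("group sizes:", cls.counts())
# A non-empty variant_specific group is the signature that distinguishes the
# variant-like interface from a second wild-type-like run.
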
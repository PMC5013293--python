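"""Extrapolate a dimer interface into a 14-subunit filament model.

Builds a dimer whose subunit B is subunit A rotated 25.7 degrees and raised
44 A (the axial subunit spacing), extrapolates the interface map, and reports the helical parameters —
25.7 deg/subunit closes one full turn in almost exactly 14 subunits.
"""

import numpy as np

import protofil as pf

prot = pf.make_protomer(n_residues=120, seed=7, marker_resseqs=())
ang = np.radians(25.7)
R = np.array([[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
frame = pf.DimerFrame(0.0, prot, prot.transformed(R, [0.0, 0.0, 44.0], label="B"))

model = pf.extrapolate_filament(frame, n_subunits=14)
h = model.helix
print(f"subunits:          {model.n_subunits}")
print(f"twist per subunit: {h.twist_per_subunit_deg:.2f} deg")
print(f"rise per subunit:  {h.rise_per_subunit_A:.2f} A")
print(f"subunits per turn: {h.subunits_per_turn:.2f}")
print(f"clashes:           {len(pf.clash_report(model))}")
pf.write_filament(model, "filament.pdb")
print("wrote filament.pdb (one chain per subunit)")
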
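# Structure-mode run for deposited coordinate models (not bundled with this
# repository; download e.g. the composite E. gracilis ATP synthase dimer,
# PDB 6TDU, to data/deposited/6tdu.cif first).
#
# The selection strings below document the intended subunit groups for the
# rotor-stator buried-area and dimer-angle computations.  Chain identifiers
# differ between depositions, so map them from the file's entity list before
# running (placeholders marked <...>):
#   - rotor:  the c-ring chains of one monomer
#   - stator: the membrane-embedded stator subunits facing the c-ring
#             (subunit a, subunit k, ATPEG4, and the lumenal ATPEG1 helix)
#   - dimer axes: each monomer's c-ring plus central stalk
mode: structure
seed: 1
output_dir: results/structure_deposited

structure:
  model_path: data/deposited/6tdu.cif
  # default lipid name set counts CDL/CL as cardiolipin and the common
  # phospholipid codes (PA, PC, PE, ...) as other lipids; water/detergent
  # codes are excluded
  lipid_names: [CDL, CL, CDN, PA, LPP, PC, PE, PG, PS, PI, POP, POV, PEE, PGV, LHG, 3PE, PTY]
  bsa:
    sel_a: "chain <c-ring chains of monomer 1>"
    sel_b: "chain <a> <k> <EG4> <EG1>"
    probe: 1.4
    n_points: 960
    halved: true          # per-side interface convention; the unhalved
                          # value is always reported alongside
  dimer_axes:
    sel_1: "chain <c-ring + central stalk, monomer 1>"
    sel_2: "chain <c-ring + central stalk, monomer 2>"
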
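# Per-element 12-6 Lennard-Jones parameters for intermolecular contacts,
# following the AutoDock 3.0.5 convention: Rii is the like-pair optimum
# separation (A) and eps the well depth (kcal/mol).  Pair parameters use
# Rij = (Rii + Rjj)/2 and eps_ij = sqrt(eps_i * eps_j).  Phosphorus is
# aliased to the sulfur values; the ruthenium row is a package default
# (soft metal well) since the docking set carries no Ru entry.
element,eps,R
C,0.150,4.00
N,0.160,3.50
O,0.200,3.20
S,0.200,4.00
P,0.200,4.00
H,0.020,2.00
Ru,0.056,2.96
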
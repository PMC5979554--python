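# Default pairwise force-field parameters for the semi-empirical binding
# free-energy model. These numbers are the published AutoDock 4.2
# free-energy-model defaults (Huey, Morris, Olson & Goodsell, J. Comput.
# Chem. 28 (2007) 1145-1152); substitute your own file to change them.
#
# Global records:
#   weight <term> <value>      term weights W_vdw W_hbond W_elec W_sol W_conf
#   sigma <value>              desolvation Gaussian width, Angstrom
#   qsolpar <value>            charge-dependent solvation increment, 1/e
#
# Per-type records (whitespace-delimited):
#   type radius well_depth solvation_param volume hbond_flag [hb_radius hb_depth]
#     radius          per-type vdW radius, Angstrom (Rij = r_i + r_j)
#     well_depth      kcal/mol (eps_ij = sqrt(eps_i * eps_j))
#     solvation_param dimensionless atomic solvation parameter S_i
#     volume          atomic fragmental volume V_i, Angstrom^3
#     hbond_flag      0 = none, 1 = donor hydrogen, 2 = acceptor
#     hb_radius       12-10 equilibrium distance for the H..acceptor pair, A
#     hb_depth        12-10 well depth, kcal/mol
weight vdw   0.1662
weight hbond 0.1209
weight elec  0.1406
weight sol   0.1322
weight conf  0.2983
sigma 3.5
qsolpar 0.01097
C   2.00  0.150  -0.00143  33.5103  0
A   2.00  0.150  -0.00052  33.5103  0
N   1.75  0.160  -0.00162  22.4493  0
NA  1.75  0.160  -0.00162  22.4493  2  1.90  5.0
O   1.60  0.200  -0.00251  17.1573  0
OA  1.60  0.200  -0.00251  17.1573  2  1.90  5.0
S   2.00  0.200  -0.00214  33.5103  0
SA  2.00  0.200  -0.00214  33.5103  2  2.50  1.0
H   1.00  0.020   0.00051   0.0000  0
HD  1.00  0.020   0.00051   0.0000  1
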
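# Isotopic masses (Da) and natural abundances (mole fraction).
# Masses: AME2020 atomic mass evaluation; abundances: IUPAC/CIAAW 2021
# representative values. Version: 2024-01.
# element	mass_number	mass_da	abundance
H	1	1.00782503224	0.999885
H	2	2.01410177812	0.000115
C	12	12.0	0.9893
C	13	13.00335483534	0.0107
N	14	14.00307400446	0.99636
N	15	15.00010889894	0.00364
O	16	15.99491461960	0.99757
O	17	16.99913175664	0.00038
O	18	17.99915961284	0.00205
F	19	18.99840316273	1.0
Na	23	22.98976928199	1.0
P	31	30.97376199842	1.0
S	32	31.97207117443	0.9499
S	33	32.97145890985	0.0075
S	34	33.96786701	0.0425
S	36	35.96708070	0.0001
Cl	35	34.96885268	0.7576
Cl	37	36.96590260	0.2424
Br	79	78.91833760	0.5069
Br	81	80.91628970	0.4931
I	127	126.90447190	1.0
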
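id,equation,reversible,basis,free
GLCupt,GLC.ext (abcdef) -> GLC (abcdef),0,1,1
HEX,GLC (abcdef) -> G6P (abcdef),0,0,0
PGI,G6P (abcdef) -> F6P (abcdef),1,0,0
PFK,F6P (abcdef) -> FBP (abcdef),0,0,0
FBA,FBP (abcdef) -> DHAP (cba) + GAP (def),1,0,0
TPI,DHAP (abc) -> GAP (abc),1,0,0
GAPDH,GAP (abc) -> PG3 (abc),0,0,0
G6PDH,G6P (abcdef) -> RUL5P (bcdef) + CO2 (a),0,0,1
RPE,RUL5P (abcde) -> XYL5P (abcde),1,0,0
RPI,RUL5P (abcde) -> RIB5P (abcde),1,0,0
TKT1,XYL5P (abcde) + RIB5P (fghij) -> GAP (cde) + SED7P (abfghij),1,0,0
TKT2,XYL5P (abcde) + E4P (fghi) -> GAP (cde) + F6P (abfghi),1,0,0
TALA,SED7P (abcdefg) + GAP (hij) -> E4P (defg) + F6P (abchij),1,0,0
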
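# Published headline tensile indices of hot-pressed spruce CTMP sheets.
# grammage 100 g/m^2; dry-pressed: mc = 7 wt %, moist-pressed: mc = 25 wt %.
# T_C empty = unpressed reference; tensile_index in N m/g.
condition,T_C,mc_pct,time_s,pressure_MPa,state,tensile_index
unpressed,,7,,,dry_test,27.7
unpressed,,7,,,wet_test,0.0
dry_pressed,280,7,3,3.5,dry_test,49.7
moist_pressed,240,25,3,3.5,dry_test,62.9
dry_pressed,300,7,3,3.5,wet_test,21.2
moist_pressed,300,25,3,3.5,wet_test,25.7
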
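# Regimen registry: every fractionation schedule used at baseline or
# reachable through the protocol-change rewrites.
# nodal_class: none = breast/chest wall only; scax = supraclavicular +
# undissected axilla; scax_imn = scax plus internal mammary chain.
regimen_id,primary_dose_gy,primary_fractions,nodal_class,dibh,boost,boost_fractions,label
40-15,40,15,none,false,false,0,40/15 whole breast or chest wall
40-15_boost,40,15,none,false,true,5,40/15 whole breast or chest wall with 5 fraction boost
40-15_dibh,40,15,none,true,false,0,40/15 whole breast or chest wall in DIBH
40-15_boost_dibh,40,15,none,true,true,5,40/15 whole breast or chest wall in DIBH with boost
40-15_scax,40,15,scax,false,false,0,40/15 + sc/ax nodes
40-15_scax_boost,40,15,scax,false,true,5,40/15 + sc/ax nodes with boost
40-15_scax_dibh,40,15,scax,true,false,0,40/15 + sc/ax nodes in DIBH
40-15_scax_boost_dibh,40,15,scax,true,true,5,40/15 + sc/ax nodes in DIBH with boost
40-15_scaximn,40,15,scax_imn,false,false,0,40/15 + sc/ax nodes + IMN
40-15_scaximn_boost,40,15,scax_imn,false,true,5,40/15 + sc/ax nodes + IMN with boost
40-15_scaximn_dibh,40,15,scax_imn,true,false,0,40/15 + sc/ax nodes + IMN in DIBH
40-15_scaximn_boost_dibh,40,15,scax_imn,true,true,5,40/15 + sc/ax nodes + IMN in DIBH with boost
50-25,50,25,none,false,false,0,50/25 whole breast or chest wall
50-25_dibh,50,25,none,true,false,0,50/25 whole breast or chest wall in DIBH
50-25_scax_dibh,50,25,scax,true,false,0,50/25 + sc/ax nodes in DIBH
50-25_scaximn_dibh,50,25,scax_imn,true,false,0,50/25 + sc/ax nodes + IMN in DIBH
26-5,26,5,none,false,false,0,26/5 whole breast or chest wall
26-5_dibh,26,5,none,true,false,0,26/5 whole breast or chest wall in DIBH
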
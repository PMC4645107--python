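# Subshell occupancies and binding energies (keV) for the shipped elements,
# plus one cross-section row per element giving the total photoabsorption
# cross section (barn) at the reference photon energy.
# Binding energies: standard X-ray data booklet values (rounded); small
# outer-shell energies are approximate.  Gd cross section at 8.48 keV is the
# adopted reference value 1.04e5 barn; the C value is 144x lower.
# Rows with an empty subshell field are cross-section rows.
element,subshell,occupancy,binding_energy_keV,sigma_total_barn,reference_energy_keV
C,1s,2,0.2842,,
C,2s,2,0.0198,,
C,2p,2,0.0089,,
C,,,,722.0,8.48
Gd,1s,2,50.239,,
Gd,2s,2,8.376,,
Gd,2p1/2,2,7.930,,
Gd,2p3/2,4,7.243,,
Gd,3s,2,1.881,,
Gd,3p1/2,2,1.688,,
Gd,3p3/2,4,1.544,,
Gd,3d3/2,4,1.2172,,
Gd,3d5/2,6,1.1852,,
Gd,4s,2,0.3758,,
Gd,4p1/2,2,0.2885,,
Gd,4p3/2,4,0.2709,,
Gd,4d,10,0.1410,,
Gd,4f,7,0.0083,,
Gd,5s,2,0.0361,,
Gd,5p,6,0.0203,,
Gd,5d,1,0.0020,,
Gd,6s,2,0.0010,,
Gd,,,,104000.0,8.48
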
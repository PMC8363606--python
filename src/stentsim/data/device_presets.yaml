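# Parametric device presets. Proprietary stent patterns are not public;
# these presets are representative ring-and-link designs carrying the
# family, strut section and alloy of the commercial devices they echo.
stents:
  integrity_like:
    family: wire
    rings: 10
    crowns_per_ring: 8
    links_per_ring_pair: 2
    strut_section: {shape: circular, diameter_mm: 0.091}
    alloy: MP35N
    nominal_diameter_mm: 3.0
    nominal_length_mm: 18.0
  onyx_like:
    family: wire
    rings: 10
    crowns_per_ring: 8
    links_per_ring_pair: 2
    strut_section: {shape: circular, diameter_mm: 0.081}
    alloy: MP35N
    core_alloy: PtIr
    core_area_fraction: 0.25
    nominal_diameter_mm: 3.0
    nominal_length_mm: 18.0
  synergy_like:
    family: laser_cut
    rings: 12
    crowns_per_ring: 8
    links_per_ring_pair: 2
    strut_section: {shape: rectangular, width_mm: 0.097, thickness_mm: 0.074}
    alloy: PtCr
    nominal_diameter_mm: 3.0
    nominal_length_mm: 16.0
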
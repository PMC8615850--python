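# Directional-lead geometry profiles (distances in mm, angles in degrees,
# measured from the physical lead tip). The Cartesia values are configuration
# defaults; verify against manufacturer documentation before clinical-style
# use.
cartesia:
  name: cartesia
  tip_to_marker_center_mm: 10.6
  tip_to_directional_levels_mm: [2.75, 4.75]
  marker_streak_offset_deg: 0.0
  star_gap_offset_deg: 0.0
  shaft_radius_mm: 0.65
  marker_half_length_mm: 1.5
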
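# Species presets: printed device and specimen dimensions.
# Lengths in µm unless suffixed otherwise; channel lengths in mm.
species:
  lily:
    tube_diameter_mean_um: 17.4
    tube_diameter_sd_um: 2.5
    grain_major_um: 128.5
    grain_minor_um: 98.3
    layout:
      n_unit_cells: 9
      channels_per_cell: 44
      chamber_depth_um: 118.5
      footprint_mm: [26.0, 10.0]
      channel:
        width_um: 25.0
        height_um: 30.0
        length_min_mm: 2.0
        length_max_mm: 3.4
    mean_guided_per_cell: 12
  arabidopsis:
    tube_diameter_mean_um: 4.9
    tube_diameter_sd_um: 0.7
    grain_major_um: 27.0
    grain_minor_um: 19.9
    layout:
      n_unit_cells: 40
      # channel count, cross-section and chamber depth of the Arabidopsis
      # variant are not published; capacity is undefined until a channel
      # count is supplied.
      channels_per_cell: null
      chamber_depth_um: null
      footprint_mm: null
      channel: null
    mean_guided_per_cell: 6
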
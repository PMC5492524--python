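# Reference camera: DJI Phantom 4 integrated RGB sensor, with the
# chessboard-calibration intrinsics used by the pipeline's distortion model.
camera:
  sensor_width_mm: 6.25
  sensor_height_mm: 4.68
  real_focal_length_mm: 3.6      # real focal length (20 mm in 35 mm-equivalent terms)
  image_width_px: 4000
  image_height_px: 3000
  pixel_pitch_um: 1.5625
flight:
  recommended_height_m: 60.0
  tested_height_range_m: [40.0, 80.0]
calibration:
  focal_length_px: [2249.5, 2249.8]
  principal_point_px: [2015.9, 1508.8]
  skew: -7.2265
  radial_coeffs: [-0.0160, -0.0336]
  tangential_coeffs: [0.0011, 5.6749e-4]
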
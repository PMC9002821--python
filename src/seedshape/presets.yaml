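# Named parameter presets for the geometric seed-shape models.
#
# Lateral models (LM) are members of a cardioid family
#   r(theta) = a * [ (1 - notch_open) * (1 + cos theta) + notch_open ]
#              * hilum window modifier,   then x *= elongate, y *= flatten
# with the cusp (hilum notch) at theta = pi. Dorsal models (DM) are
# super-ellipses |x/a|^n + |y/b|^n = 1.
#
# LM1 and DM1(n=2) are exact (cardioid, ellipse). The other presets are this
# package's documented approximations of the published model silhouettes,
# which are distributed as raster images and can be loaded directly with
# load_model_image for exact comparisons.
LM1: {a: 1.0}
LM2: {a: 1.0, flatten: 0.80}                                   # flattened cardioid
LM3: {a: 1.0, notch_open: 0.50}                                # open cardioid
LM4: {a: 1.0, flatten: 0.85, elongate: 1.20}                   # flattened + elongated
LM5: {a: 1.0, notch_open: 0.50, hilum: 0.35}                   # open, hilum filled
LM6: {a: 1.0, notch_open: 0.50, hilum: -0.35}                  # open, hilum deepened
LM7: {a: 1.0, flatten: 0.90, notch_open: 0.30, hilum: 0.25}
LM8: {a: 1.0, flatten: 0.90, elongate: 1.10, notch_open: 0.20, hilum: -0.20}
DM1: {a: 1.0, b: 0.62, n: 2.0}                                 # ellipse
DM5: {a: 1.0, b: 0.62, n: 2.5}
DM6: {a: 1.0, b: 0.52, n: 2.5}                                 # narrower than DM5
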
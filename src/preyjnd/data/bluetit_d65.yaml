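# Default viewer: synthetic blue tit under synthetic 6504 K daylight.
#
# The sensitivity table is a synthetic stand-in built from the Govardovskii
# A1 visual-pigment template with logistic ocular-media and oil-droplet
# filters at nominal blue tit peak wavelengths (UVS 371, SWS 448, MWS 503,
# LWS 563 nm; double cone LWS-based), NOT a measured whole-eye table.  The
# illuminant is a 6504 K Planck curve normalised to 100 at 560 nm.  Cone
# abundances default to UVS:SWS:MWS:LWS = 1 : 1.92 : 2.68 : 2.7, so the
# LWS cone is the most abundant and anchors the 0.05 Weber fraction.
name: bluetit_d65
sensitivities: bluetit_cones_synthetic.csv
channels: [UVS, SWS, MWS, LWS]
double_cone: double
abundances: [1.0, 1.92, 2.68, 2.7]
weber_ref: 0.05
weber_double: 0.05
illuminant: d65_synthetic.csv
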
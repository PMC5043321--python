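# Example visual-system configuration for a zebra finch-like tetrachromat.
#
# Pigment peaks, oil-droplet cut-offs and the ocular-media shape below are
# REPRESENTATIVE LITERATURE VALUES for passerine (UVS-type) retinas, shipped
# so the synthetic pipeline runs out of the box.  They are not measured
# constants of any particular study; replace them (or point `table:` entries
# at tabulated sensitivity CSVs) for quantitative work on real spectra.

receptors:
  UVS:
    lambda_max: 365          # UVS cone; oil droplet transparent (no filter)
  SWS:
    lambda_max: 430
    droplet_cut_nm: 415
    droplet_slope: 0.06
  MWS:
    lambda_max: 505
    droplet_cut_nm: 505
    droplet_slope: 0.06
  LWS:
    lambda_max: 565
    droplet_cut_nm: 560
    droplet_slope: 0.06

double_cone:
  lambda_max: 565            # principal member; pale P-type droplet
  droplet_cut_nm: 420
  droplet_slope: 0.04

ocular_media:
  half_point_nm: 325         # logistic long-pass model of lens + cornea
  slope_per_nm: 0.08

weber_lws: 0.1               # limiting Weber fraction of the LWS channel
abundances: {UVS: 1.0, SWS: 1.5, MWS: 2.0, LWS: 3.0}
noise_scaling: sqrt          # omega_i = v / sqrt(eta_i)
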
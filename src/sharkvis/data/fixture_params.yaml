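# All tunable constants of the synthetic fixtures, in one auditable place.
# EEM components are 2-D Gaussians: efficiency(ex, em) =
#   amp * exp(-((ex-ex_center)/ex_sigma)^2/2) * exp(-((em-em_center)/em_sigma)^2/2)
# (anti-Stokes entries zeroed, whole matrix rescaled to quantum_yield_max).

msp:
  scan_lo_nm: 350
  scan_hi_nm: 700
  default_noise_sd: 0.05

species:
  C_ventriosum:
    lambda_max_nm: 484.0
    eem_components:
      # broad deep-UV extract band (dominant in the methanol-extract matrix)
      - {name: uv_extract, amp: 3.0, ex_center: 310, ex_sigma: 20, em_center: 410, em_sigma: 55}
      # dark-patch blue band: 455 nm emission under 355 nm excitation
      - {name: blue_skin, amp: 1.0, ex_center: 345, ex_sigma: 22, em_center: 455, em_sigma: 25}
      # shoulder of the blue band toward 500 nm
      - {name: blue_shoulder, amp: 0.25, ex_center: 345, ex_sigma: 22, em_center: 505, em_sigma: 20}
      # green skin band: 525-535 nm emission under 390 and 470 nm excitation
      - {name: green_skin, amp: 1.0, ex_center: 435, ex_sigma: 40, em_center: 530, em_sigma: 14}
  S_retifer:
    lambda_max_nm: 488.0
    eem_components:
      - {name: uv_extract, amp: 3.5, ex_center: 285, ex_sigma: 18, em_center: 350, em_sigma: 45}
      - {name: blue_skin, amp: 1.0, ex_center: 345, ex_sigma: 22, em_center: 455, em_sigma: 25}
      - {name: blue_shoulder, amp: 0.25, ex_center: 345, ex_sigma: 22, em_center: 505, em_sigma: 20}
      - {name: green_skin, amp: 1.0, ex_center: 435, ex_sigma: 40, em_center: 530, em_sigma: 14}

eem_grids:
  excitation: {lo: 250, hi: 550, step: 5}
  emission: {lo: 300, hi: 650, step: 1}

# peak photons emitted per excitation photon (absolute quantum efficiencies
# are not published; ratio/argmax results do not depend on this value)
quantum_yield_max: 0.1

patches:
  beige:
    reflectance_lo: 0.30   # at 300 nm, rising linearly to
    reflectance_hi: 0.40   # at 700 nm
    fluorescence_scale: 1.0
  dark:
    reflectance_lo: 0.05
    reflectance_hi: 0.07
    fluorescence_scale: 0.05

alignment:
  genes: {ND2: 1047, COI: 647, RAG1: 2475}
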
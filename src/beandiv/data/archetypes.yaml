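# Default gene-pool archetypes for the synthetic collection generator.
#
# These are INVENTED defaults: the means follow published group-level
# summaries for Andean-like and Mesoamerican-like common bean germplasm
# (large speckled seeds, erect/determinate plants, white-pink flowers
# versus small speckle-free seeds on prostrate indeterminate plants);
# the standard deviations and all probability vectors are plausible
# choices, not estimates from any accession-level dataset.
#
# quantitative: trait -> [mean, sd] in trait units
# qualitative:  trait -> {level code: probability}
# LWS is derived (seed length / seed width) and is recomputed after each
# draw; its entry here is documentation only.
andean:
  name: Andean
  quantitative:
    DF: [45.0, 5.0]
    DM: [74.0, 6.0]
    PH: [65.0, 15.0]
    NS: [11.0, 2.0]
    NB: [4.0, 1.0]
    NP: [7.5, 2.0]
    PL: [12.5, 1.8]
    PW: [1.2, 0.15]
    NSP: [4.5, 1.0]
    SL: [1.65, 0.15]
    SW: [0.95, 0.08]
    LWS: [1.74, 0.15]
    HSW: [42.0, 5.0]
  qualitative:
    HP: {1: 0.75, 2: 0.25}
    GH: {1: 0.85, 2: 0.15}
    PHA: {1: 0.80, 2: 0.20}
    ST: {1: 0.85, 2: 0.15}
    LS: {1: 0.85, 2: 0.15}
    CS: {1: 0.45, 2: 0.25, 3: 0.20, 4: 0.05, 5: 0.05}
    CW: {1: 0.45, 2: 0.25, 3: 0.20, 4: 0.05, 5: 0.05}
    PC: {1: 0.15, 2: 0.50, 3: 0.25, 4: 0.10}
    SP: {1: 0.15, 2: 0.50, 3: 0.15, 4: 0.10, 5: 0.05, 6: 0.05}
    SPA: {1: 0.80, 2: 0.20}
    PS: {1: 0.60, 2: 0.25, 3: 0.15}
    SS: {1: 0.35, 2: 0.35, 6: 0.15, 8: 0.15}
    SCC: {1: 0.35, 2: 0.15, 5: 0.15, 7: 0.20, 10: 0.15}
    SSC: {0: 0.05, 1: 0.60, 2: 0.25, 3: 0.10}
    CSSC: {0: 0.05, 1: 0.20, 2: 0.40, 4: 0.10, 5: 0.25}
    HC: {1: 0.40, 2: 0.35, 3: 0.25}
mesoamerican:
  name: Mesoamerican
  quantitative:
    DF: [50.0, 5.0]
    DM: [79.0, 5.0]
    PH: [190.0, 40.0]
    NS: [16.0, 3.0]
    NB: [6.0, 1.5]
    NP: [10.3, 2.5]
    PL: [10.5, 1.5]
    PW: [0.95, 0.12]
    NSP: [6.0, 1.2]
    SL: [1.05, 0.10]
    SW: [0.65, 0.06]
    LWS: [1.62, 0.15]
    HSW: [22.0, 4.0]
  qualitative:
    HP: {1: 0.60, 2: 0.40}
    GH: {1: 0.05, 2: 0.95}
    PHA: {1: 0.10, 2: 0.90}
    ST: {1: 0.70, 2: 0.30}
    LS: {1: 0.70, 2: 0.30}
    CS: {1: 0.10, 2: 0.05, 3: 0.05, 4: 0.35, 5: 0.45}
    CW: {1: 0.10, 2: 0.05, 3: 0.05, 4: 0.35, 5: 0.45}
    PC: {1: 0.10, 2: 0.40, 3: 0.30, 4: 0.20}
    SP: {1: 0.10, 4: 0.40, 6: 0.25, 7: 0.15, 8: 0.10}
    SPA: {1: 0.85, 2: 0.15}
    PS: {1: 0.50, 2: 0.30, 3: 0.20}
    SS: {2: 0.15, 4: 0.15, 6: 0.20, 7: 0.50}
    SCC: {2: 0.20, 3: 0.30, 4: 0.30, 6: 0.10, 8: 0.10}
    SSC: {0: 0.90, 1: 0.05, 2: 0.05}
    CSSC: {0: 0.90, 1: 0.05, 3: 0.05}
    HC: {1: 0.30, 2: 0.50, 3: 0.20}
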
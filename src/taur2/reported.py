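"""Published MM-GBSA component means for tau R2 binding to microtubules.

Means (kcal/mol) over the last 150 ns of five independent trajectories
per system, as reported for the wild-type R2 repeat and its
phosphoserine variants.  ``tds_wsas`` is the weighted-SASA entropy
term; ``tds_interaction`` the interaction-entropy term.  These are
inputs to the assembly arithmetic (ΔG_bind = ΔE_vdw + ΔE_eel +
ΔG_p^sol + ΔG_np^sol − TΔS), never outputs of this package.
"""

from types import MappingProxyType

REPORTED_COMPONENTS = MappingProxyType({
    "R2-WT": {
        "de_vdw": -110.3, "de_eel": -2158.4, "dg_polar": 2200.7,
        "dg_nonpolar": -16.7, "tds_wsas": -44.8, "tds_interaction": -31.1,
    },
    "R2-pSer289": {
        "de_vdw": -99.0, "de_eel": -1168.9, "dg_polar": 1232.4,
        "dg_nonpolar": -15.0, "tds_wsas": -41.8, "tds_interaction": -28.6,
    },
    "R2-pSer293": {
        "de_vdw": -88.7, "de_eel": -1158.2, "dg_polar": 1205.1,
        "dg_nonpolar": -13.4, "tds_wsas": -42.9, "tds_interaction": -27.2,
    },
    "R2-pSer289+pSer293": {
        "de_vdw": -120.2, "de_eel": -214.2, "dg_polar": 306.0,
        "dg_nonpolar": -17.5, "tds_wsas": -44.4, "tds_interaction": -26.9,
    },
})

SYSTEMS = tuple(REPORTED_COMPONENTS)
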
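"""Published kinetic conditions for WT and K289M pol β on the four substrates.

Globally fitted rate constants for the four enzyme/sequence conditions
(wild type and the K289M colon-cancer variant, on the control and APC
primer-templates), biochemical single-turnover constants, the fidelity
table, and the LFER slopes. These serve as generating truths for the
synthetic-data recovery experiments.

Not every rate constant of every condition is available in the source
text: the nucleotide K_D values, the post-chemistry reopening rate, and a
few reverse rates were reported only graphically or in supplementary
material. Those fields are SYNTHETIC STAND-INS — plausible values chosen
once, flagged per condition in :data:`STAND_IN_FIELDS` — and no analysis
in this package treats them as measured.
"""

from __future__ import annotations

import pandas as pd

from .parameters import RateParameters

__all__ = [
    "FIGURE_CONDITIONS",
    "STAND_IN_FIELDS",
    "KPOL_BIOCHEMICAL",
    "LFER_SLOPES",
    "FIDELITY_TABLE",
    "SEQUENCES",
]

# Stand-in values shared across conditions (literature-typical magnitudes):
#   KD_dNTP = 10 μM; kon near diffusion limit; post-chemistry reopening 10 s⁻¹.
_COMMON = dict(KD_dNTP=10.0, kon_dNTP=100.0, k4r=0.0, k5f=10.0, k5r=0.0)

#: Globally fitted rate constants per condition (s⁻¹ unless noted).
FIGURE_CONDITIONS: dict[str, RateParameters] = {
    # WT, control sequence: fast closing, NCS comparable to chemistry.
    "wt_control": RateParameters(
        k2f=173.0, k2r=2.1, k3f=24.0, k3r=19.8, k4f=16.6, **_COMMON
    ),
    # K289M, control sequence: ~3-fold slower closing, chemistry rate-limiting.
    "k289m_control": RateParameters(
        k2f=63.0, k2r=2.0, k3f=18.0, k3r=17.6, k4f=1.3, **_COMMON
    ),
    # WT, APC sequence: NCS dramatically accelerated (207 vs 24 s⁻¹).
    "wt_apc": RateParameters(
        k2f=159.0, k2r=2.0, k3f=207.0, k3r=20.0, k4f=20.0, **_COMMON
    ),
    # K289M, APC sequence: the NCS collapses to 1 s⁻¹ and becomes
    # rate-limiting (18-fold slower than on the control sequence, and
    # slower than chemistry at 12 s⁻¹).
    "k289m_apc": RateParameters(
        k2f=42.0, k2r=2.0, k3f=1.0, k3r=22.2, k4f=12.0, **_COMMON
    ),
}

#: Fields of each condition that are synthetic stand-ins, not reported values.
STAND_IN_FIELDS: dict[str, tuple[str, ...]] = {
    "wt_control": ("KD_dNTP", "kon_dNTP", "k5f", "k5r"),
    "k289m_control": ("KD_dNTP", "kon_dNTP", "k2r", "k5f", "k5r"),
    "wt_apc": ("KD_dNTP", "kon_dNTP", "k2r", "k3r", "k4f", "k5f", "k5r"),
    "k289m_apc": ("KD_dNTP", "kon_dNTP", "k2r", "k5f", "k5r"),
}

#: Biochemical single-turnover rate constants (value, SE), s⁻¹.
KPOL_BIOCHEMICAL: dict[str, tuple[float, float]] = {
    "wt_control": (12.6, 1.1),
    "k289m_control": (1.5, 0.1),
}

#: LFER slopes of log10(kpol) vs leaving-group pKa4 per enzyme and sequence.
#: Near-zero slope = chemistry not rate-limiting for that condition.
LFER_SLOPES: dict[str, dict[str, float]] = {
    "wt": {
        "control": -0.46,
        "apc": -0.41,
        "control_in_apc": -0.52,
        "apc_in_control": -0.42,
        "ttgtt": -0.69,
        "aagaa": -0.69,
        "aaaaa": -0.74,
    },
    "k289m": {
        "control": -0.27,
        "apc": -0.07,
        "control_in_apc": -0.24,
        "apc_in_control": -0.06,
        "ttgtt": -0.38,
        "aagaa": -0.61,
        "aaaaa": -0.07,
    },
}


def _fidelity_table() -> pd.DataFrame:
    rows = [
        ("wt", "control", "C:C", 12.0, 1.0),
        ("wt", "apc", "C:C", 2.4, 4.8),
        ("wt", "control_in_apc", "C:C", 20.0, 0.6),
        ("wt", "apc_in_control", "C:C", 7.9, 1.5),
        ("wt", "aagaa", "G:G", 8.7, 1.3),
        ("wt", "aaaaa", "A:G", 2.0, 5.6),
        ("k289m", "control", "C:C", 5.9, 1.9),
        ("k289m", "apc", "C:C", 0.4, 31.1),
        ("k289m", "control_in_apc", "C:C", 5.3, 2.2),
        ("k289m", "apc_in_control", "C:C", 1.5, 7.5),
        ("k289m", "aagaa", "G:G", 7.9, 1.5),
        ("k289m", "aaaaa", "A:G", 2.0, 5.7),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "enzyme",
            "sequence",
            "template_incoming",
            "fidelity_1e4",  # fidelity in units of 10^4
            "loss_vs_wt_control",  # WT-control fidelity / fidelity
        ],
    )


#: Measured fidelity (×10⁴) and loss relative to WT on the control sequence.
FIDELITY_TABLE: pd.DataFrame = _fidelity_table()

#: Primer-template substrates (single-nucleotide-gap duplexes; the gap sits
#: after position 22 of the upper strand; templating base is C in all four).
SEQUENCES: dict[str, tuple[str, str]] = {
    "control": (
        "GCCTATTACCGCGCAGATGCGC GTCGGAACAACGCATGCCGTCC",
        "CGGATAATGGCGCGTCTACGCGCCAGCCTTGTTGCGTACGGCAGG",
    ),
    "apc": (
        "GCCTCGAACTCCATATGGATTT TTCAGAACGCTCGGTTGCGTCC",
        "CGGAGCTTGAGGTATACCTAAACAAGTCTTGCGAGCCAACGCAGG",
    ),
    "control_in_apc": (
        "GCCTCGAACTCCATATGGATGC GTCAGAACGCTCGGTTGCGTCC",
        "CGGAGCTTGAGGTATACCTACGCCAGTCTTGCGAGCCAACGCAGG",
    ),
    "apc_in_control": (
        "GCCTATTACCGCGCAGATGCTT TTCGGAACAACGCATGCCGTCC",
        "CGGATAATGGCGCGTCTACGAACAAGCCTTGTTGCGTACGGCAGG",
    ),
}
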
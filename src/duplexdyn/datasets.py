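"""Published photophysical parameters for the 2-aminopurine-labeled duplexes.

Reported decay-associated quantities for the single strand (C2ApC) and the
four duplexes formed against T, C, 5-methyl-C and 5-hydroxymethyl-C at the
variable position.  Lifetimes are in ns, amplitudes A_i and fractional
intensities f_i are dimensionless, tau_av in ns, rates in 1e7 s^-1.  These
values serve as worked-example inputs: the derived columns (f_i, tau_av,
k_r, k_nr) are recomputable from the primary ones with the functions in
:mod:`duplexdyn.photophysics`.
"""

from __future__ import annotations

REPORTED_PHOTOPHYSICS: dict[str, dict] = {
    "C2ApC": {
        "lifetimes_ns": (0.61, 2.35, 10.00),
        "amplitudes": (0.53, 0.21, 0.27),
        "fractional": (0.09, 0.14, 0.76),
        "tau_av_ns": 3.47,
        "k_r_1e7": 0.49,
        "k_nr_1e7": 28.34,
        "qy": 0.0173,
    },
    "C2ApC/GTG": {
        "lifetimes_ns": (0.61, 2.35, 10.00),
        "amplitudes": (0.21, 0.32, 0.42),
        "fractional": (0.03, 0.15, 0.83),
        "tau_av_ns": 5.12,
        "k_r_1e7": 0.09,
        "k_nr_1e7": 19.45,
        "qy": 0.0049,
    },
    "C2ApC/GCG": {
        "lifetimes_ns": (0.61, 2.35, 10.00),
        "amplitudes": (0.25, 0.32, 0.44),
        "fractional": (0.03, 0.14, 0.83),
        "tau_av_ns": 5.27,
        "k_r_1e7": 0.11,
        "k_nr_1e7": 18.87,
        "qy": 0.0063,
    },
    "C2ApC/GmCG": {
        "lifetimes_ns": (0.61, 2.35, 10.00),
        "amplitudes": (0.24, 0.33, 0.43),
        "fractional": (0.03, 0.15, 0.82),
        "tau_av_ns": 5.18,
        "k_r_1e7": 0.11,
        "k_nr_1e7": 19.19,
        "qy": 0.0059,
    },
    "C2ApC/GhmCG": {
        "lifetimes_ns": (0.61, 2.35, 10.00),
        "amplitudes": (0.24, 0.31, 0.45),
        "fractional": (0.03, 0.14, 0.83),
        "tau_av_ns": 5.35,
        "k_r_1e7": 0.18,
        "k_nr_1e7": 18.50,
        "qy": 0.0100,
    },
}

# Reported duplex melting midpoints (degC) from fluorescence-detected curves.
REPORTED_TM: dict[str, float] = {
    "C2ApC/GTG": 59.5,
    "C2ApC/GCG": 50.11,
}
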
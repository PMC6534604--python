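"""Built-in calibration-group data.

Eight healthy young near-emmetropic subjects (right eyes): autorefractor
readings, aberrometer pupil diameter d_w with second-to-fourth-order
OSA/ANSI Zernike coefficients (units of the 555 nm reference wavelength;
defocus excluded except for the myopic subject K. M.), mean acuity-test
pupil diameter d_m, measured acuity V_m, and the acuity simulated with
the average neural model (sigma = 0.10, delta_rho = 0.0025), V_ave, kept
for regression testing.  Coefficients above fourth order were part of the
original tenth-order measurements but are not published; they are zero
here.
"""

# (n, m) -> coefficient in lambda0 units
SUBJECTS = {
    "GA": {
        "RE_D": 0.0, "Cyl_D": -0.5, "d_w_mm": 4.5, "d_m_mm": 4.6,
        "V_m": -0.27, "V_ave": -0.22,
        "coeffs": {
            (2, -2): -1.32e-1, (2, 2): -1.59e-1,
            (3, -3): -4.15e-2, (3, -1): -4.09e-2, (3, 1): -3.32e-2, (3, 3): 7.52e-2,
            (4, -4): 4.86e-2, (4, -2): 4.02e-2, (4, 0): 2.98e-2,
            (4, 2): -6.97e-2, (4, 4): 7.45e-2,
        },
    },
    "MT": {
        "RE_D": 0.25, "Cyl_D": 0.5, "d_w_mm": 6.2, "d_m_mm": 5.6,
        "V_m": -0.22, "V_ave": -0.21,
        "coeffs": {
            (2, -2): -3.57e-2, (2, 2): -2.54e-1,
            (3, -3): -2.68e-1, (3, -1): -3.81e-1, (3, 1): 6.28e-2, (3, 3): 1.40e-1,
            (4, -4): -4.13e-2, (4, -2): 5.40e-3, (4, 0): 9.23e-2,
            (4, 2): 6.07e-2, (4, 4): -7.46e-2,
        },
    },
    "PB": {
        "RE_D": 0.5, "Cyl_D": 0.5, "d_w_mm": 5.8, "d_m_mm": 4.8,
        "V_m": -0.18, "V_ave": -0.19,
        "coeffs": {
            (2, -2): 4.34e-1, (2, 2): 1.91e-1,
            (3, -3): 3.43e-1, (3, -1): -2.09e-2, (3, 1): -7.65e-2, (3, 3): -4.06e-2,
            (4, -4): 9.23e-2, (4, -2): -3.86e-2, (4, 0): 2.27e-1,
            (4, 2): 1.36e-1, (4, 4): 2.90e-2,
        },
    },
    "ST": {
        "RE_D": 0.25, "Cyl_D": 0.0, "d_w_mm": 5.4, "d_m_mm": 5.6,
        "V_m": -0.25, "V_ave": -0.21,
        "coeffs": {
            (2, -2): 1.42e-1, (2, 2): -1.39e-1,
            (3, -3): -6.18e-2, (3, -1): 2.02e-1, (3, 1): 2.93e-1, (3, 3): 8.87e-2,
            (4, -4): -4.35e-2, (4, -2): 5.55e-3, (4, 0): -5.71e-2,
            (4, 2): 5.94e-2, (4, 4): -3.04e-2,
        },
    },
    "UF": {
        "RE_D": 0.25, "Cyl_D": -0.25, "d_w_mm": 2.9, "d_m_mm": 3.8,
        "V_m": -0.31, "V_ave": -0.33,
        "coeffs": {
            (2, -2): -4.63e-3, (2, 2): 6.81e-2,
            (3, -3): -1.22e-2, (3, -1): 1.70e-2, (3, 1): 1.05e-2, (3, 3): -4.59e-3,
            (4, -4): 1.45e-3, (4, -2): 4.80e-3, (4, 0): 5.53e-3,
            (4, 2): 3.67e-3, (4, 4): 2.19e-3,
        },
    },
    "KM": {
        "RE_D": -0.5, "Cyl_D": -1.25, "d_w_mm": 6.3, "d_m_mm": 6.0,
        "V_m": -0.09, "V_ave": -0.05,
        "coeffs": {
            (2, 0): -2.24, (2, -2): 1.82e-1, (2, 2): 1.15,
            (3, -3): -1.63e-2, (3, -1): -7.06e-2, (3, 1): -1.06e-1, (3, 3): -1.20e-2,
            (4, -4): 4.61e-3, (4, -2): 4.35e-2, (4, 0): 9.13e-2,
            (4, 2): 1.20e-2, (4, 4): 6.06e-2,
        },
    },
    "SO": {
        "RE_D": 1.5, "Cyl_D": 0.0, "d_w_mm": 6.2, "d_m_mm": 5.0,
        "V_m": -0.24, "V_ave": -0.26,
        "coeffs": {
            (2, -2): 3.93e-1, (2, 2): -1.93e-1,
            (3, -3): -3.31e-1, (3, -1): 1.45e-1, (3, 1): -6.66e-3, (3, 3): 1.42e-1,
            (4, -4): -3.68e-2, (4, -2): 6.14e-2, (4, 0): 1.98e-1,
            (4, 2): -4.30e-2, (4, 4): -1.05e-2,
        },
    },
    "GT": {
        "RE_D": 0.0, "Cyl_D": -0.25, "d_w_mm": 6.2, "d_m_mm": 6.0,
        "V_m": -0.25, "V_ave": -0.21,
        "coeffs": {
            (2, -2): 2.11e-1, (2, 2): 2.21e-2,
            (3, -3): -3.29e-2, (3, -1): -2.31e-1, (3, 1): 5.65e-2, (3, 3): 5.84e-2,
            (4, -4): -4.91e-2, (4, -2): 4.53e-2, (4, 0): 1.21e-1,
            (4, 2): -5.39e-2, (4, 4): -7.90e-3,
        },
    },
}

#: Individually calibrated neural parameters and fitting errors, kept for
#: reference and plausibility checks (not used by the average model).
INDIVIDUAL_CALIBRATION = {
    "GA": {"V_bf": -0.26, "dRR": 0.025, "sigma": 0.075, "delta_rho": 0.002},
    "MT": {"V_bf": -0.21, "dRR": 0.060, "sigma": 0.150, "delta_rho": 0.002},
    "PB": {"V_bf": -0.16, "dRR": 0.047, "sigma": 0.125, "delta_rho": 0.003},
    "ST": {"V_bf": -0.23, "dRR": 0.050, "sigma": 0.100, "delta_rho": 0.002},
    "UF": {"V_bf": -0.30, "dRR": 0.033, "sigma": 0.150, "delta_rho": 0.003},
    "KM": {"V_bf": -0.07, "dRR": 0.047, "sigma": 0.125, "delta_rho": 0.002},
    "SO": {"V_bf": -0.23, "dRR": 0.039, "sigma": 0.150, "delta_rho": 0.003},
    "GT": {"V_bf": -0.25, "dRR": 0.034, "sigma": 0.075, "delta_rho": 0.002},
}

#: Pooled average-model neural parameters.
AVERAGE_SIGMA = 0.10
AVERAGE_DELTA_RHO = 0.0025
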
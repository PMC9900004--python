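"""Published reference values for oral florfenicol in rainbow trout.

Tissue pharmacokinetic parameters reported for a single 15 mg/kg oral
dose of florfenicol (FF) and its metabolite florfenicol amine (FFA) in
rainbow trout reared at ~17 degC, and muscle residue data from a 30-day
medicated-feed trial (1x/3x/5x/10x of 10 mg/kg/day) with 20 days of
depuration. These are literature values, not outputs of this package;
they serve as inputs for consistency checks (the reported tables are
linked by the standard NCA identities) and as realistic targets for the
synthetic-data generator.

Units: times h, concentrations ug/kg, AUC h*ug/kg, rate constants 1/h.
"""

from __future__ import annotations

#: Sampling schedule of the single-dose study, hours post dose.
SINGLE_DOSE_SCHEDULE = (0.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 16.0, 24.0,
                        32.0, 48.0, 64.0, 96.0, 128.0)

SINGLE_DOSE_MGKG = 15.0

#: Reported parent-drug (FF) parameters by tissue.
#: t_half: terminal half-life (h); T: mean lifetime t_half/ln2 (h);
#: lam: decay constant 1/T (1/h); tmax (h); cmax (ug/kg);
#: auc_0_128 (h*ug/kg); auc_ratio: AUC(tissue)/AUC(plasma);
#: k_el (1/h); auc_tail: AUC(128-inf); auc_0_inf; ka = ln2/t_half (1/h);
#: c_last: concentration at 128 h (ug/kg).
FF_TISSUE_PARAMS = {
    "plasma":    {"t_half": 23.34, "T": 33.67, "lam": 0.029, "tmax": 16.0,
                  "cmax": 273.0, "auc_0_128": 7735.43, "auc_ratio": None,
                  "k_el": 0.03489, "auc_tail": 32.6713, "auc_0_inf": 7768.10,
                  "ka": 0.030, "c_last": 1.14},
    "skin":      {"t_half": 25.13, "T": 36.26, "lam": 0.027, "tmax": 24.0,
                  "cmax": 569.0, "auc_0_128": 17964.7, "auc_ratio": 4.55,
                  "k_el": 0.03143, "auc_tail": 221.099, "auc_0_inf": 18185.8,
                  "ka": 0.028, "c_last": 6.95},
    "muscle":    {"t_half": 22.04, "T": 31.80, "lam": 0.03, "tmax": 24.0,
                  "cmax": 431.0, "auc_0_128": 13076.4, "auc_ratio": 2.32,
                  "k_el": 0.03503, "auc_tail": 48.5261, "auc_0_inf": 13124.9,
                  "ka": 0.031, "c_last": 1.7},
    "liver":     {"t_half": 20.93, "T": 30.19, "lam": 0.033, "tmax": 16.0,
                  "cmax": 973.0, "auc_0_128": 35202.0, "auc_ratio": 1.69,
                  "k_el": 0.02433, "auc_tail": 480.814, "auc_0_inf": 35682.8,
                  "ka": 0.033, "c_last": 11.7},
    "kidney":    {"t_half": 22.70, "T": 32.75, "lam": 0.030, "tmax": 16.0,
                  "cmax": 2250.0, "auc_0_128": 31468.1, "auc_ratio": 4.06,
                  "k_el": 0.03334, "auc_tail": 311.896, "auc_0_inf": 31780.0,
                  "ka": 0.031, "c_last": 10.4},
    "gill":      {"t_half": 19.39, "T": 27.97, "lam": 0.035, "tmax": 16.0,
                  "cmax": 2890.0, "auc_0_128": 43779.0, "auc_ratio": 5.65,
                  "k_el": 0.03869, "auc_tail": 183.210, "auc_0_inf": 43962.2,
                  "ka": 0.036, "c_last": 7.09},
    "intestine": {"t_half": 28.62, "T": 41.29, "lam": 0.024, "tmax": 16.0,
                  "cmax": 5360.0, "auc_0_128": 107043.1, "auc_ratio": 13.83,
                  "k_el": 0.022512, "auc_tail": 3722.423, "auc_0_inf": 110765.5,
                  "ka": 0.024, "c_last": 83.8},
}

#: Reported metabolite (FFA) parameters by tissue; MR is the published
#: metabolite ratio AUC_FFA/AUC_FF. Negative k_el values are reported as
#: published (rising terminal metabolite data in skin and kidney).
FFA_TISSUE_PARAMS = {
    "plasma":    {"t_half": 33.82, "T": 48.79, "tmax": 16.0, "cmax": 61.0,
                  "auc_0_128": 1647.46, "k_el": 0.01216, "mr": 0.213,
                  "ka": 0.020},
    "skin":      {"t_half": 50.07, "T": 72.24, "tmax": 32.0, "cmax": 64.7,
                  "auc_0_128": 3543.68, "k_el": -0.0218, "mr": 0.197,
                  "ka": 0.014},
    "muscle":    {"t_half": 16.75, "T": 24.17, "tmax": 24.0, "cmax": 36.1,
                  "auc_0_128": 985.702, "k_el": 0.00241, "mr": 0.075,
                  "ka": 0.041},
    "liver":     {"t_half": 31.39, "T": 45.28, "tmax": 24.0, "cmax": 41.7,
                  "auc_0_128": 2238.43, "k_el": 0.01099, "mr": 0.064,
                  "ka": 0.022},
    "kidney":    {"t_half": 86.95, "T": 125.44, "tmax": 64.0, "cmax": 258.0,
                  "auc_0_128": 15294.8, "k_el": -0.0241, "mr": 0.486,
                  "ka": 0.008},
    "gill":      {"t_half": 19.74, "T": 28.48, "tmax": 32.0, "cmax": 61.3,
                  "auc_0_128": 2076.76, "k_el": 0.01359, "mr": 0.047,
                  "ka": 0.035},
    "intestine": {"t_half": 20.28, "T": 29.27, "tmax": 32.0, "cmax": 34.4,
                  "auc_0_128": 1053.239, "k_el": 0.007328, "mr": 0.010,
                  "ka": 0.034},
}

#: Published apparent metabolic rate (AMR) and apparent distribution rate
#: (ADR) summary values by tissue.
AMR_ADR_TABLE = {
    "plasma":    {"amr": 0.175, "adr": 0.129},
    "skin":      {"amr": 0.164, "adr": 0.027},
    "muscle":    {"amr": 0.070, "adr": 0.022},
    "liver":     {"amr": 0.059, "adr": 0.038},
    "kidney":    {"amr": 0.327, "adr": 0.049},
    "gill":      {"amr": 0.045, "adr": 0.024},
    "intestine": {"amr": 0.009, "adr": 0.006},
}

#: 30-day medicated-feed biosafety trial: therapeutic dose and multipliers.
BIOSAFETY_DOSE_MGKG = 10.0
BIOSAFETY_MULTIPLIERS = (1, 3, 5, 10)
BIOSAFETY_DOSING_DAYS = 30
BIOSAFETY_DEPURATION_DAYS = 20
BIOSAFETY_SAMPLING_DAYS = (10.0, 20.0, 30.0, 40.0, 50.0)

#: Reported parent-drug muscle residues (ug/kg): the peak observed in each
#: dose group (with its day) and the day-50 residue after depuration.
MUSCLE_RESIDUE_FF = {
    "1x":  {"peak": 2160.0, "peak_day": 20.0, "day50": 1.32},
    "3x":  {"peak": 1630.0, "peak_day": 20.0, "day50": 0.407},
    "5x":  {"peak": 1410.0, "peak_day": 30.0, "day50": 0.911},
    "10x": {"peak": 2810.0, "peak_day": 10.0, "day50": 0.102},
}

#: Metabolite muscle residues (ug/kg): peak and day-50 values per group.
MUSCLE_RESIDUE_FFA = {
    "1x":  {"peak": 1210.0, "peak_day": 10.0, "day50": 1.99},
    "3x":  {"peak": 350.0,  "peak_day": 10.0, "day50": 2.95},
    "5x":  {"peak": 1140.0, "peak_day": 10.0, "day50": 6.01},
    "10x": {"peak": 8660.0, "peak_day": 10.0, "day50": 12.7},
}

#: EMA maximum residue limit for florfenicol marker residue in fish
#: muscle, ug/kg.
MRL_MUSCLE_UGKG = 1000.0
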
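"""Summary toxicokinetic results of the in-vivo gestation study.

The raw concentration records of the study were not deposited; what is
published are the summary 24-h AUCs per matrix and gestational day —
observed (``obs``, composite curves from the measured concentrations) and
model-estimated (``est``) — plus the study's limit-of-quantification table.
These values serve as worked-example inputs for the ratio machinery and as
the reference design for the synthetic-study generator.

Units: ug.h/ml for blood, ug.h/g for tissues.  Missing entries (below-LOQ
or not applicable) are absent from the maps.
"""

from __future__ import annotations

from .pk import ratios

__all__ = [
    "AUC_MATERNAL",
    "AUC_FETAL_CIS",
    "SC_KTRANS",
    "LOQ_MG_PER_L",
    "reported_auc_map",
    "INTEXT_RATIO_PAIRS",
    "intext_ratios",
]

# maternal 24-h AUCs: {isomer: {matrix: {gd: {"obs"|"est": value}}}}
AUC_MATERNAL: dict[str, dict[str, dict[int, dict[str, float]]]] = {
    "cis": {
        "blood": {1: {"obs": 1.26, "est": 1.60}, 15: {"obs": 6.71, "est": 7.72}, 20: {"obs": 7.52, "est": 6.53}},
        "liver": {1: {"obs": 6.20, "est": 4.72}, 15: {"obs": 21.22, "est": 11.79}, 20: {"obs": 15.79, "est": 10.75}},
        "brain": {1: {"obs": 4.80, "est": 3.88}, 15: {"obs": 10.28, "est": 8.07}, 20: {"obs": 7.05, "est": 6.86}},
        "kidney": {1: {"obs": 12.89, "est": 9.45}, 15: {"obs": 20.34, "est": 21.59}, 20: {"est": 18.26}},
        "fat": {1: {"obs": 43.97, "est": 37.18}, 15: {"obs": 1247.08, "est": 1171.88}, 20: {"obs": 1260.18, "est": 1357.83}},
        "mammary": {1: {"obs": 21.23, "est": 22.06}, 15: {"obs": 606.71, "est": 690.07}, 20: {"obs": 856.41, "est": 840.45}},
        "placenta": {15: {"obs": 23.92, "est": 12.80}, 20: {"obs": 17.67, "est": 16.13}},
    },
    "trans": {
        "blood": {1: {"est": 0.42}, 15: {"obs": 1.18, "est": 0.75}, 20: {"obs": 1.04, "est": 0.61}},
        "liver": {15: {"est": 1.54}, 20: {"est": 0.95}},
        "brain": {1: {"est": 0.52}, 15: {"obs": 0.77, "est": 0.71}, 20: {"obs": 0.53, "est": 0.59}},
        "fat": {1: {"obs": 10.60, "est": 10.06}, 15: {"obs": 34.41, "est": 44.10}, 20: {"obs": 61.77, "est": 53.29}},
        "mammary": {1: {"est": 3.94}, 15: {"obs": 73.20, "est": 46.66}, 20: {"obs": 37.53, "est": 44.18}},
        "placenta": {15: {"est": 1.72}, 20: {"est": 2.26}},
    },
}

# fetal 24-h AUCs at GD20 (cis-isomer; litter-pooled samples)
AUC_FETAL_CIS: dict[str, dict[str, float]] = {
    "blood": {"obs": 3.35, "est": 1.66},
    "liver": {"obs": 17.86, "est": 8.18},
    "brain": {"obs": 3.83, "est": 2.94},
}

# posterior-mean placental transfer constants (L/h/kg^0.75)
SC_KTRANS: dict[str, float] = {"dam_to_fetus": 1.91, "fetus_to_dam": 2.52}

# limits of quantification, converted to mg/L (= ug/ml = ug/g); fetal
# matrices reuse the corresponding maternal LOQ
LOQ_MG_PER_L: dict[tuple[str, str], float] = {
    ("cis", "blood"): 0.026,
    ("cis", "liver"): 0.020,
    ("cis", "brain"): 0.020,
    ("cis", "fat"): 0.020,
    ("cis", "mammary"): 0.020,
    ("cis", "kidney"): 0.040,
    ("cis", "placenta"): 0.004,
    ("cis", "feces"): 0.004,
    ("cis", "fetal_blood"): 0.026,
    ("cis", "fetal_liver"): 0.020,
    ("cis", "fetal_brain"): 0.020,
    ("trans", "blood"): 0.052,
    ("trans", "liver"): 0.080,
    ("trans", "brain"): 0.020,
    ("trans", "fat"): 0.080,
    ("trans", "mammary"): 0.080,
    ("trans", "kidney"): 0.080,
    ("trans", "placenta"): 0.020,
    ("trans", "feces"): 0.040,
    ("trans", "fetal_blood"): 0.052,
    ("trans", "fetal_liver"): 0.080,
    ("trans", "fetal_brain"): 0.020,
}


def reported_auc_map() -> dict[str, float]:
    """Flat key -> AUC map (keys like ``"cis/fat/gd15/obs"``)."""
    out: dict[str, float] = {}
    for iso, tissues in AUC_MATERNAL.items():
        for mat, by_gd in tissues.items():
            for gd, kinds in by_gd.items():
                for kind, v in kinds.items():
                    out[f"{iso}/{mat}/gd{gd}/{kind}"] = v
    for mat, kinds in AUC_FETAL_CIS.items():
        for kind, v in kinds.items():
            out[f"cis/fetal_{mat}/gd20/{kind}"] = v
    out["sc_ktrans1"] = SC_KTRANS["dam_to_fetus"]
    out["sc_ktrans2"] = SC_KTRANS["fetus_to_dam"]
    return out


#: the worked ratios quoted in the study's results, as (numerator, denominator)
INTEXT_RATIO_PAIRS: dict[str, tuple[str, str]] = {
    # feto-maternal exposure
    "fm_brain_obs": ("cis/fetal_brain/gd20/obs", "cis/brain/gd20/obs"),  # 0.54
    "fm_blood_est": ("cis/fetal_blood/gd20/est", "cis/blood/gd20/est"),  # 0.25
    # placenta relative to blood (observed)
    "placenta_blood_gd15_obs": ("cis/placenta/gd15/obs", "cis/blood/gd15/obs"),  # 3.6
    "placenta_blood_gd20_obs": ("cis/placenta/gd20/obs", "cis/blood/gd20/obs"),  # 2.3
    # accumulation after repeated dosing (observed, vs GD1)
    "blood_gd15_gd1": ("cis/blood/gd15/obs", "cis/blood/gd1/obs"),  # 5.3
    "blood_gd20_gd1": ("cis/blood/gd20/obs", "cis/blood/gd1/obs"),  # 6
    "fat_gd15_gd1": ("cis/fat/gd15/obs", "cis/fat/gd1/obs"),  # 28.4
    "fat_gd20_gd1": ("cis/fat/gd20/obs", "cis/fat/gd1/obs"),  # 28.7
    "mammary_gd15_gd1": ("cis/mammary/gd15/obs", "cis/mammary/gd1/obs"),  # 28.6
    "mammary_gd20_gd1": ("cis/mammary/gd20/obs", "cis/mammary/gd1/obs"),  # 40.3
    # placental transfer asymmetry
    "sc_ktrans1_over_2": ("sc_ktrans1", "sc_ktrans2"),  # 0.76
}


def intext_ratios() -> dict[str, float]:
    """Recompute every worked ratio from the published summary AUCs."""
    return ratios(reported_auc_map(), INTEXT_RATIO_PAIRS)
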
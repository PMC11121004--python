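"""Published national-cohort reference tables (Latvia, AF/flutter, 2012-2022).

These are the printed summary tables of the national reimbursement-claims
study this package's pipeline reproduces in structure: the yearly
prescription counts per active substance, the prescribed-by-dispensed
conformity cross-tabulation for the four DOACs, the adherence-group
characteristics table, and a handful of headline cohort counts. They are
inputs (small, exact, as printed), not outputs of this package; the
pipeline's ``reproduce`` command recomputes derived quantities from them
and checks the printed headline values.
"""

from __future__ import annotations

import pandas as pd

YEARS = list(range(2012, 2023))

#: Yearly prescription counts per active substance (AF/flutter cohort).
#: Zero means the substance was not prescribed that year.
YEARLY_PRESCRIPTIONS: dict[str, dict[int, int]] = {
    "aethacizine": {2012: 7322, 2013: 9369, 2014: 11150, 2015: 14132, 2016: 16688,
                    2017: 19006, 2018: 22515, 2019: 26852, 2020: 30007, 2021: 31203,
                    2022: 33518},
    "amiodarone": {2012: 16521, 2013: 15922, 2014: 15457, 2015: 15298, 2016: 14839,
                   2017: 14388, 2018: 14575, 2019: 14781, 2020: 12741, 2021: 10969,
                   2022: 10319},
    "apixaban": {2020: 4, 2021: 340, 2022: 2296},
    "atenolol": {2012: 40, 2013: 29, 2014: 43, 2015: 28, 2016: 64, 2017: 47,
                 2018: 26, 2019: 45, 2020: 32, 2021: 14},
    "dabigatran": {2018: 10736, 2019: 22994, 2020: 25227, 2021: 23040, 2022: 19963},
    "digoxin": {2012: 2933, 2013: 3175, 2014: 3493, 2015: 3880, 2016: 4123,
                2017: 4497, 2018: 4705, 2019: 4886, 2020: 5214, 2021: 5349,
                2022: 5177},
    "diltiazem": {2012: 191, 2013: 173, 2014: 148, 2015: 116, 2016: 115, 2017: 109,
                  2018: 85, 2019: 105, 2020: 64, 2021: 35, 2022: 37},
    "edoxaban": {2019: 679, 2020: 15904, 2021: 37074, 2022: 56226},
    "clopidogrel": {2012: 354, 2013: 1958, 2014: 3688, 2015: 5025, 2016: 6083,
                    2017: 6577, 2018: 6179, 2019: 5561, 2020: 4733, 2021: 3895,
                    2022: 3274},
    "clopidogrel/aspirin": {2012: 57, 2013: 1244, 2014: 2142, 2015: 2702, 2016: 2738,
                            2017: 2320, 2018: 2089, 2019: 1812, 2020: 1432,
                            2021: 1150, 2022: 773},
    "metoprolol": {2012: 5110, 2013: 5861, 2014: 5843, 2015: 5823, 2016: 6144,
                   2017: 6335, 2018: 6248, 2019: 6975, 2020: 6275, 2021: 5857,
                   2022: 5700},
    "propafenone": {2012: 3765, 2013: 4624, 2014: 5349, 2015: 6440, 2016: 7423,
                    2017: 8128, 2018: 9350, 2019: 10810, 2020: 10929, 2021: 10751,
                    2022: 11054},
    "rivaroxaban": {2018: 23571, 2019: 81625, 2020: 113940, 2021: 130922,
                    2022: 139989},
    "warfarin": {2012: 13689, 2013: 17366, 2014: 22107, 2015: 26266, 2016: 29970,
                 2017: 33276, 2018: 35326, 2019: 34591, 2020: 31344, 2021: 25987,
                 2022: 20410},
    "verapamil": {2012: 600, 2013: 522, 2014: 500, 2015: 485, 2016: 464, 2017: 486,
                  2018: 470, 2019: 274, 2020: 241, 2021: 268, 2022: 253},
    "others": {2012: 11, 2013: 6, 2014: 3, 2015: 29, 2016: 18, 2017: 5, 2018: 7,
               2019: 1, 2020: 4, 2021: 4, 2022: 5},
}

#: Prescribed (substance, mg) by dispensed (substance, mg) prescription counts
#: for the DOAC sub-cohort. Absent cells are zero.
DOAC_CROSSTAB: dict[tuple[str, float], dict[tuple[str, float], int]] = {
    ("apixaban", 2.5): {("apixaban", 2.5): 1215, ("apixaban", 5.0): 16},
    ("apixaban", 5.0): {("apixaban", 2.5): 10, ("apixaban", 5.0): 1399},
    ("dabigatran", 110.0): {("dabigatran", 110.0): 50334,
                            ("dabigatran", 150.0): 595,
                            ("rivaroxaban", 15.0): 1},
    ("dabigatran", 150.0): {("dabigatran", 110.0): 740,
                            ("dabigatran", 150.0): 50242},
    ("dabigatran", 75.0): {("dabigatran", 110.0): 1, ("dabigatran", 150.0): 1},
    ("edoxaban", 15.0): {("edoxaban", 30.0): 14, ("edoxaban", 60.0): 1,
                         ("rivaroxaban", 15.0): 3},
    ("edoxaban", 30.0): {("dabigatran", 150.0): 1, ("edoxaban", 30.0): 53223,
                         ("edoxaban", 60.0): 472, ("rivaroxaban", 15.0): 3,
                         ("rivaroxaban", 20.0): 2},
    ("edoxaban", 60.0): {("edoxaban", 30.0): 624, ("edoxaban", 60.0): 55490,
                         ("rivaroxaban", 15.0): 2, ("rivaroxaban", 20.0): 1},
    ("rivaroxaban", 10.0): {("rivaroxaban", 15.0): 19, ("rivaroxaban", 20.0): 22},
    ("rivaroxaban", 15.0): {("dabigatran", 150.0): 3, ("rivaroxaban", 15.0): 211346,
                            ("rivaroxaban", 20.0): 2127},
    ("rivaroxaban", 20.0): {("rivaroxaban", 15.0): 2965,
                            ("rivaroxaban", 20.0): 273455},
}

#: Stated size of the DOAC prescription sub-cohort (the cross-tab's own cell
#: sum is slightly smaller; both denominators are supported downstream).
DOAC_COHORT_PRESCRIPTIONS = 704_521

#: Adherence-group characteristics (n = 45,933 scored patients).
ADHERENCE_GROUPS = pd.DataFrame(
    [
        {"group": "below_80", "n": 25615, "age_mean": 75.1, "age_sd": 9.7,
         "female_n": 15116, "warfarin_to_doac_n": 7328, "among_doacs_n": 3515},
        {"group": "from_80_to_90", "n": 10483, "age_mean": 75.0, "age_sd": 9.4,
         "female_n": 6434, "warfarin_to_doac_n": 3071, "among_doacs_n": 1034},
        {"group": "above_90", "n": 9835, "age_mean": 74.8, "age_sd": 9.8,
         "female_n": 5805, "warfarin_to_doac_n": 2583, "among_doacs_n": 458},
    ]
)

#: Distinct-anticoagulant counts among the 39,181 switcher patients.
SWITCHER_DISTINCT_COUNTS = {2: 32842, 3: 6324, 4: 608, 5: 15}
SWITCHERS_TOTAL = 39_181
ANTICOAGULATED_PATIENTS = 93_721
COHORT_PATIENTS = 104_524
ADHERENCE_ASSESSED_PATIENTS = 45_933
ADHERENCE_EXCLUDED_LT2 = 201

#: Headline values as printed in the published report, used by the
#: ``reproduce`` command as pass/fail references for recomputation.
REPORTED = {
    "doac_mismatch_rate_pct": 1.1,
    "doac_mismatch_count": 7623,
    "rivaroxaban_share_2022_pct": 45.3,
    "total_prescriptions_2012_2022": 1_646_648,
    "adherence_above_80_share_pct": 44.2,
    "switchers_two_agents_share_pct": 83.8,
}

#: Reported paper-form prescription shares (%) for selected years.
PAPER_FORM_SHARE_PCT = {2017: 98.5, 2018: 19.4, 2022: 1.3}
#: Reported INN prescribing shares (%) for selected years.
INN_SHARE_PCT = {2018: 2.6, 2019: 3.1, 2020: 61.2, 2021: 80.6, 2022: 79.7}


def yearly_table() -> pd.DataFrame:
    """Long-format yearly utilisation counts: columns year, substance, n."""
    rows = [
        {"year": y, "substance": sub, "n": counts.get(y, 0)}
        for sub, counts in YEARLY_PRESCRIPTIONS.items()
        for y in YEARS
        if counts.get(y, 0) > 0
    ]
    return pd.DataFrame(rows).sort_values(["year", "substance"]).reset_index(drop=True)


def doac_crosstab() -> pd.DataFrame:
    """The DOAC conformity cross-tab as a prescribed-by-dispensed count matrix."""
    keys_rx = sorted(DOAC_CROSSTAB)
    keys_disp = sorted({k for row in DOAC_CROSSTAB.values() for k in row})
    mat = pd.DataFrame(0, index=pd.MultiIndex.from_tuples(keys_rx),
                       columns=pd.MultiIndex.from_tuples(keys_disp))
    for rx, row in DOAC_CROSSTAB.items():
        for disp, n in row.items():
            mat.loc[rx, disp] = n
    mat.index.names = ["prescribed_substance", "prescribed_strength"]
    mat.columns.names = ["dispensed_substance", "dispensed_strength"]
    return mat
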
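"""Published case counts from the FAERS 2004Q1-2023Q1 GLP-1 RA study.

These are the printed report counts of the published psychiatric
adverse-event case series for GLP-1 receptor agonists; they serve as *inputs*
when reproducing that study's descriptive arithmetic (shares, percentages,
onset-bin fractions) through this package's own computation paths.  Only
counts are stored — every percentage is recomputed at run time.
"""

from __future__ import annotations

#: Per-regimen report counts: (psychiatric-AE cases, all AE cases).
TABLE1_COUNTS: dict[str, tuple[int, int]] = {
    "overall": (8_240, 181_238),
    "exenatide": (3_948, 72_377),
    "liraglutide": (1_152, 28_980),
    "lixisenatide": (12, 311),
    "dulaglutide": (1_833, 52_158),
    "semaglutide": (1_033, 17_741),
    "tirzepatide": (262, 9_671),
}

#: Size of the psychiatric-AE case series.
CASE_SERIES_N = 8_240

#: Sex distribution of the case series.
SEX_COUNTS: dict[str, int] = {"women": 5_429, "men": 2_551, "unknown": 260}

#: Reporting region distribution of the case series.
REGION_COUNTS: dict[str, int] = {
    "North America": 7_673, "Europe": 299, "Asia": 137, "South America": 68,
    "Oceania": 47, "Africa": 7, "unknown": 9,
}

#: Reporter occupation counts (consumer / physician dominate).
OCCUPATION_COUNTS: dict[str, int] = {
    "consumer": 6_577, "physician": 694, "pharmacist": 137,
    "health professional": 161, "other health professional": 202,
    "lawyer": 12, "unknown": 457,
}

#: Indication-group counts.
INDICATION_COUNTS: dict[str, int] = {
    "diabetes mellitus": 5_286, "weight control": 332,
    "blood glucose abnormal": 78, "others": 263, "unknown": 2_281,
}

#: Outcome counts (one slot per report; unknown = no outcome listed).
OUTCOME_COUNTS: dict[str, int] = {
    "death": 79, "life threatening": 43, "hospitalization": 883,
    "disability": 111, "congenital anomaly": 1,
    "required intervention to prevent": 14, "other medical event": 1_064,
    "unknown": 6_045,
}

#: Per-regimen case counts within the case series (sums to CASE_SERIES_N).
REGIMEN_CASE_COUNTS: dict[str, int] = {
    "exenatide": 3_948, "liraglutide": 1_152, "lixisenatide": 12,
    "dulaglutide": 1_833, "semaglutide": 1_033, "tirzepatide": 262,
}

#: Usable time-to-onset counts over the conventional bins, overall series.
ONSET_BIN_COUNTS: dict[str, int] = {
    "0-30": 734, "30-60": 206, "60-90": 102, "90-120": 57, "120-150": 42,
    "150-180": 29, "180-360": 118, "360+": 223,
}

#: The eight published positive signal PTs with report count and ROR (95% CI).
SIGNAL_PTS: dict[str, tuple[int, float, float, float]] = {
    "NERVOUSNESS": (941, 1.97, 1.85, 2.11),
    "STRESS": (770, 1.28, 1.19, 1.38),
    "EATING DISORDER": (289, 1.57, 1.40, 1.77),
    "FEAR OF INJECTION": (97, 1.96, 1.60, 2.40),
    "SLEEP DISORDER DUE TO GENERAL MEDICAL CONDITION-INSOMNIA TYPE":
        (75, 2.01, 1.60, 2.52),
    "BINGE EATING": (21, 2.70, 1.75, 4.16),
    "FEAR OF EATING": (8, 3.35, 1.65, 6.78),
    "SELF-INDUCED VOMITING": (7, 3.77, 1.77, 8.03),
}
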
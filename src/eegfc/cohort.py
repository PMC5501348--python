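"""Clinical cohort table: subject demographics and Fugl-Meyer scores.

The reference cohort is 30 first-time stroke survivors with persistent
upper-limb coordination deficits who underwent 12 weeks of intensive
therapy.  The upper-extremity portion of the Fugl-Meyer assessment (FMUE,
integer 0-66) was scored before and after the intervention; its change
(dFMUE = post - pre) is the functional-recovery outcome every biomarker is
validated against.
"""

from __future__ import annotations

import io

import pandas as pd

COHORT_COLUMNS = [
    "Patient", "Months post insult", "Type", "Location", "Affected arm",
    "FMUE_Pre", "FMUE_Post",
]

# Demographics of the 30-subject reference cohort.
# SCWM: subcortical white matter; IC: internal capsule.
_COHORT_CSV = """\
Patient,Months post insult,Type,Location,Affected arm,FMUE_Pre,FMUE_Post
1,18,Ischemic,Cortex,R,19,19
2,12,Ischemic,SCWM,R,38,49
3,16,Ischemic,Cortex,R,14,27
4,22,Hemorrhagic,Subarachnoid,R,41,55
5,24,Ischemic,Cortex,L,21,32
6,16,Ischemic,Basal ganglia/IC,R,18,38
7,24,Ischemic,Cortex,R,23,30
8,49,Ischemic,Cortex,R,10,20
9,28,Ischemic,Basal ganglia/IC,R,27,47
10,28,Ischemic,Cortex,L,26,48
11,14,Ischemic,SCWM,R,23,29
12,26,Ischemic,Cortex,L,18,25
13,21,Ischemic,Cortex,L,23,33
14,8,Ischemic,Cortex,L,44,52
15,14,Ischemic,Cortex,L,17,20
16,22,Ischemic,Cortex,L,16,18
17,15,Hemorrhagic,Basal ganglia,R,16,20
18,13,Ischemic,Cortex,R,16,23
19,9,Ischemic,Cortex,R,49,58
20,17,Ischemic,Cortex,R,13,17
21,17,Ischemic,Cortex,R,16,27
22,20,Ischemic,Basal ganglia/IC,R,34,40
23,21,Ischemic,Cortex,R,21,27
24,9,Hemorrhagic,Lobar,R,24,33
25,11,Hemorrhagic,Lobar,R,26,33
26,43,Hemorrhagic,Basal ganglia,R,26,41
27,63,Ischemic,Cortex and subcortex,R,8,18
28,20,Ischemic,Brainstem/pons,R,19,39
29,47,Hemorrhagic,Basal ganglia,L,20,36
30,26,Ischemic,Brainstem/pons,R,42,52
"""


def derive_delta(table: pd.DataFrame) -> pd.DataFrame:
    """Attach the dFMUE = FMUE_Post - FMUE_Pre column; validate score range."""
    table = table.copy()
    for col in ("FMUE_Pre", "FMUE_Post"):
        bad = ~table[col].between(0, 66)
        if bad.any():
            raise ValueError(f"{col} outside the 0-66 FMUE range for rows "
                             f"{table.index[bad].tolist()}")
    table["dFMUE"] = table["FMUE_Post"] - table["FMUE_Pre"]
    return table


def paper_cohort_fixture() -> pd.DataFrame:
    """The packaged 30-subject reference cohort with derived dFMUE."""
    return derive_delta(pd.read_csv(io.StringIO(_COHORT_CSV)))


def cortex_subgroup(table: pd.DataFrame) -> pd.DataFrame:
    """Subjects whose lesion location involves the cerebral cortex.

    Membership is a case-insensitive substring match on the location field,
    which includes mixed locations such as "Cortex and subcortex" (but not
    the SCWM abbreviation, which denotes purely subcortical white matter).
    """
    mask = table["Location"].str.contains("cortex", case=False)
    return table[mask]


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV in the reference column layout; derives dFMUE."""
    table = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    return derive_delta(table)


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    """Write a cohort table in the reference column layout (no dFMUE)."""
    table[COHORT_COLUMNS].to_csv(path, index=False)
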
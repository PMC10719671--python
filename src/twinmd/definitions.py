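"""Shared symptom/criterion definitions for DSM-IV major depression.

The interview records 14 disaggregated symptom items; the weight/appetite,
sleep, and psychomotor items are collapsed (logical OR) into single criteria
to obtain the nine official DSM MD "A" criteria.
"""

from __future__ import annotations

# 14 disaggregated interview items, in interview order.
ITEMS: tuple[str, ...] = (
    "depressed_mood",
    "anhedonia",
    "weight_decrease",
    "weight_increase",
    "appetite_decrease",
    "appetite_increase",
    "insomnia",
    "hypersomnia",
    "psychomotor_agitation",
    "psychomotor_retardation",
    "fatigue",
    "difficulty_concentrating",
    "worthlessness",
    "thoughts_of_death",
)

# Nine aggregated DSM criteria, in reporting order.
CRITERIA: tuple[str, ...] = (
    "mood",
    "interest",
    "weight_problems",
    "sleep_problems",
    "psychomotor_problems",
    "fatigue",
    "concentration",
    "worthlessness",
    "thoughts_of_death",
)

# criterion -> indices into ITEMS collapsed by OR
CRITERION_ITEMS: dict[str, tuple[int, ...]] = {
    "mood": (0,),
    "interest": (1,),
    "weight_problems": (2, 3, 4, 5),
    "sleep_problems": (6, 7),
    "psychomotor_problems": (8, 9),
    "fatigue": (10,),
    "concentration": (11,),
    "worthlessness": (12,),
    "thoughts_of_death": (13,),
}

# A-criterion cardinal symptoms: depressed mood or loss of interest.
CARDINAL_CRITERIA: tuple[int, ...] = (0, 1)

# Minimum number of criteria in a syndrome for an algorithmic MD diagnosis.
MD_CRITERION_COUNT: int = 5

N_ITEMS = len(ITEMS)
N_CRITERIA = len(CRITERIA)

# Zygosity groups as recorded per twin (same-sex MZ, same-sex DZ,
# opposite-sex); opposite-sex pairs are necessarily DZ.
ZYGOSITY_GROUPS: tuple[str, ...] = ("MZ-ss", "DZ-ss", "OS")
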
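"""Synthetic clinical cohort tables with planted patient subgroups.

Emulates the variable inventory of a prodromal-synucleinopathy (iRBD)
case–control study: demographics, sleep questionnaires (RBDSQ, PSQI, ESS),
motor scales (MDS-UPDRS subscores), timed motor tests (9-hole peg test,
10 m walk, five-time sit-to-stand, dual-task cost of the timed-up-and-go),
neuropsychological scores, raw gait side/task measures, and binary
non-motor symptoms.  Patients carry a planted two-subgroup structure in
which subgroup "B" is older and scores worse on the affected variables —
the directional severity gradient such cohorts report; the magnitudes are
generator configuration, expressed in within-group standard deviations.

Noise model: Gaussian for continuous variables (clamped to each variable's
floor, so no negative timed measures), Bernoulli for binary variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import GowerSpec

__all__ = ["VariableDef", "variable_registry", "default_effect_profile",
           "make_clinical_table", "gower_spec_from_registry"]


@dataclass(frozen=True)
class VariableDef:
    name: str
    kind: str                  # continuous | binary
    higher_is_worse: bool
    control_mean: float        # probability of 1 for binary
    patient_mean: float
    sd: float = 0.0            # unused for binary
    floor: float | None = None
    ceil: float | None = None


def variable_registry() -> list:
    """The cohort's variable inventory with baseline generator levels."""
    def c(name, worse, cm, pm, **k):
        return VariableDef(name, "continuous", worse, cm, pm, **k)

    def b(name, worse, cm, pm, **k):
        return VariableDef(name, "binary", worse, cm, pm, **k)
    return [
        c("age", True, 62.8, 62.4, sd=7.0, floor=40, ceil=90),
        c("disease_duration", True, 0.0, 5.8, sd=1.6, floor=0),
        c("rbdsq", True, 0.5, 9.2, sd=1.6, floor=0, ceil=13),
        c("psqi", True, 2.5, 5.6, sd=2.9, floor=0, ceil=21),
        c("ess", True, 3.6, 4.2, sd=2.3, floor=0, ceil=24),
        c("updrs_i", True, 0.3, 3.7, sd=3.0, floor=0),
        c("updrs_ii", True, 0.1, 0.6, sd=1.2, floor=0),
        c("updrs_iii", True, 0.5, 5.9, sd=2.7, floor=0),
        c("digit_span_backward", False, 4.9, 4.7, sd=1.1, floor=0),
        c("rey_immediate", False, 51.0, 46.6, sd=7.5, floor=0),
        c("rey_delayed", False, 11.4, 9.4, sd=2.4, floor=0),
        c("raven_matrices", False, 33.1, 31.4, sd=3.4, floor=0, ceil=36),
        c("attentive_matrices", False, 54.8, 54.6, sd=5.0, floor=0, ceil=60),
        c("token_test", False, 34.5, 34.5, sd=1.2, floor=0, ceil=36),
        c("benson_copy", False, 15.7, 15.0, sd=1.0, floor=0, ceil=17),
        c("benson_recall", False, 11.3, 10.8, sd=2.5, floor=0, ceil=17),
        c("nine_hpt", True, 21.2, 22.6, sd=3.1, floor=5),
        c("walk_10m", True, 8.0, 8.2, sd=1.0, floor=3),
        c("tsts_5", True, 10.5, 11.3, sd=2.4, floor=4),
        c("dt_cost_tug", True, 6.8, 9.7, sd=10.0, floor=-100),
        # raw gait measures feeding the asymmetry / dual-task-cost metrics
        c("stride_length_right", False, 1.30, 1.22, sd=0.12, floor=0.3),
        c("stride_length_left", False, 1.30, 1.20, sd=0.12, floor=0.3),
        c("arm_swing_right", False, 28.0, 24.0, sd=5.0, floor=2),
        c("arm_swing_left", False, 28.0, 22.0, sd=5.0, floor=2),
        c("tug_st", True, 9.0, 9.6, sd=1.3, floor=4),
        c("tug_dt", True, 9.6, 10.7, sd=1.8, floor=4),
        b("sex_male", False, 0.60, 0.75),
        b("olfactory_loss", True, 0.02, 0.42),
        b("constipation", True, 0.04, 0.25),
        b("urinary_dysfunction", True, 0.04, 0.25),
        b("orthostatic_hypotension", True, 0.02, 0.05),
        b("depressive_symptoms", True, 0.10, 0.08),
    ]


def default_effect_profile() -> dict:
    """Planted subgroup-B shifts, in within-group SD units for continuous
    variables (sign applied toward the "worse" direction) and absolute
    probability shifts for binary variables."""
    return {
        "age": 3.0, "rbdsq": 2.25, "psqi": 2.25, "ess": 3.0,
        "updrs_i": 3.0, "updrs_iii": 2.25,
        "rey_immediate": 2.25, "rey_delayed": 2.25, "raven_matrices": 3.0,
        "attentive_matrices": 2.25, "token_test": 2.25,
        "nine_hpt": 3.0, "tsts_5": 2.25, "dt_cost_tug": 2.25,
        "stride_length_right": 2.25, "stride_length_left": 2.25,
        "arm_swing_right": 2.25, "arm_swing_left": 3.0,
        "tug_dt": 2.25,
        "constipation": 0.65, "urinary_dysfunction": 0.65,
    }


def gower_spec_from_registry(registry=None, exclude=()) -> GowerSpec:
    registry = registry or variable_registry()
    variables = {v.name: ("continuous" if v.kind == "continuous" else "binary")
                 for v in registry if v.name not in exclude}
    return GowerSpec(variables=variables)


def make_clinical_table(n_controls: int = 52, n_patients: int = 44,
                        subgroup_fractions=(0.6, 0.4),
                        effect_profile: dict | None = None,
                        seed: int = 0) -> pd.DataFrame:
    """Generate the cohort table; deterministic given ``seed``.

    ``subgroup_fractions`` split the patients into planted subgroups
    ("A", "B", ...); ``effect_profile`` (default
    :func:`default_effect_profile`) is applied to the last subgroup, which
    plays the "worse disease course" role.  ``truth_cluster`` records the
    planted label for every patient and is empty for controls.
    """
    if n_controls < 0 or n_patients < 0:
        raise ValueError("cohort sizes must be non-negative")
    fractions = np.asarray(subgroup_fractions, float)
    if np.any(fractions < 0) or abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("subgroup_fractions must be non-negative and sum to 1")
    registry = variable_registry()
    names = {v.name for v in registry}
    effect_profile = (default_effect_profile() if effect_profile is None
                      else dict(effect_profile))
    unknown = set(effect_profile) - names
    if unknown:
        raise ValueError(f"effect_profile names unknown variables: "
                         f"{sorted(unknown)}")

    rng = np.random.default_rng(seed)
    counts = np.diff(np.round(np.cumsum(np.concatenate([[0], fractions]))
                              * n_patients).astype(int))
    sub_labels = ["".join(chr(ord("A") + i)) for i in range(len(counts))]
    truth = sum([[lab] * int(c) for lab, c in zip(sub_labels, counts)], [])

    rows = []
    for i in range(n_controls + n_patients):
        is_patient = i >= n_controls
        cluster = truth[i - n_controls] if is_patient else ""
        worse = is_patient and cluster == sub_labels[-1]
        row = {"id": f"{'P' if is_patient else 'C'}{i:03d}",
               "group": "patient" if is_patient else "control",
               "truth_cluster": cluster}
        for v in registry:
            base = v.patient_mean if is_patient else v.control_mean
            if v.kind == "binary":
                p = base
                if worse and v.name in effect_profile:
                    p = p + effect_profile[v.name]
                val = int(rng.random() < np.clip(p, 0.0, 1.0))
            else:
                mean = base
                if worse and v.name in effect_profile:
                    shift = effect_profile[v.name] * v.sd
                    mean = mean + (shift if v.higher_is_worse else -shift)
                val = rng.normal(mean, v.sd)
                if v.floor is not None:
                    val = max(val, v.floor)
                if v.ceil is not None:
                    val = min(val, v.ceil)
            row[v.name] = val
        rows.append(row)
    return pd.DataFrame(rows)
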
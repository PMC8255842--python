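"""Signed multi-criteria prognostic miRNA screen over a tumor cohort.

Each candidate miRNA is tested against four clinical endpoints:

* overall survival — median split of expression, log-rank test; sign ``+``
  when the high-expression group has the longer Kaplan–Meier median survival
  (favorable association);
* T stage and pathological stage — Spearman correlation with the ordinal
  stage (1–4); sign is the sign of rho;
* distant metastasis (M stage) — two-sided Mann–Whitney U between M0 and M1;
  sign ``+`` when M1 tumors express more.

A sign is reported as 0 whenever p >= alpha.  Significant endpoints are then
combined into a biomarker call: an *oncogenic* pattern is (survival −,
stage +, M +), a *tumor-suppressor* pattern the mirror image; at least two
significant endpoints are required, mixed significant orientations yield
``none`` with a conflict flag, and a miRNA is *promising* when all three
endpoint groups (survival; T-or-pathological stage; M stage) agree
significantly.

Raw p-values at alpha are used by default — the screen is a discovery filter,
not a confirmatory analysis; Benjamini–Hochberg correction per endpoint is
available as an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "ENDPOINTS",
    "CohortDataset",
    "AssociationRecord",
    "BiomarkerCall",
    "filter_mirnas",
    "survival_association",
    "stage_association",
    "metastasis_association",
    "classify_biomarker",
    "volcano_and_venn",
    "PrognosticScreen",
    "ScreenResults",
]

ENDPOINT_SURVIVAL = "survival"
ENDPOINT_T = "T_stage"
ENDPOINT_P = "P_stage"
ENDPOINT_M = "M_stage"
ENDPOINTS = (ENDPOINT_SURVIVAL, ENDPOINT_T, ENDPOINT_P, ENDPOINT_M)

ONCOGENIC = "oncogenic"
SUPPRESSOR = "suppressor"
NONE = "none"

#: endpoint sign that marks the oncogenic (poor-prognosis) orientation
_ONCO_SIGNS = {
    ENDPOINT_SURVIVAL: "-",
    ENDPOINT_T: "+",
    ENDPOINT_P: "+",
    ENDPOINT_M: "+",
}

_P_FLOOR = 1e-300  # keep -log10(p) finite


@dataclass(frozen=True)
class AssociationRecord:
    """Signed association of one miRNA with one clinical endpoint."""

    mirna_id: str
    endpoint: str
    effect: float
    sign: str  # "+", "-", or "0"
    p: float
    n_used: int
    applicable: bool = True

    @property
    def significant(self) -> bool:
        return self.applicable and self.sign != "0"


@dataclass(frozen=True)
class BiomarkerCall:
    """Combined oncogenic / suppressor / none classification of one miRNA."""

    mirna_id: str
    klass: str
    endpoints_significant: tuple[str, ...]
    promising: bool
    conflict: bool = False


@dataclass
class CohortDataset:
    """miRNA expression matrix plus per-patient clinical table.

    ``expression``: miRNAs × samples, log2(TPM+1)-like.  ``clinical``: indexed
    by sample id with columns os_days, os_event, t_stage, p_stage, m_stage;
    any clinical field may be missing per patient.  Samples are aligned to the
    intersection on construction.
    """

    expression: pd.DataFrame
    clinical: pd.DataFrame

    def __post_init__(self) -> None:
        shared = [s for s in self.expression.columns if s in self.clinical.index]
        if not shared:
            raise ValueError("expression and clinical tables share no samples")
        self.expression = self.expression[shared]
        self.clinical = self.clinical.loc[shared]
        times = self.clinical["os_days"].dropna()
        if (times <= 0).any():
            raise ValueError("survival times must be positive where present")


def filter_mirnas(expression: pd.DataFrame, min_expressed_samples: int = 300) -> pd.DataFrame:
    """Keep miRNAs detected (>0) in more than ``min_expressed_samples`` patients."""
    detected = (expression > 0).sum(axis=1)
    return expression.loc[detected > min_expressed_samples]


def _not_applicable(mirna_id: str, endpoint: str, n: int) -> AssociationRecord:
    return AssociationRecord(
        mirna_id, endpoint, float("nan"), "0", float("nan"), n, applicable=False
    )


def _km_median(times: np.ndarray, events: np.ndarray) -> float:
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    return float(kmf.median_survival_time_)


def survival_association(
    mirna_id: str,
    expression: pd.Series,
    os_days: pd.Series,
    os_event: pd.Series,
    alpha: float = 0.05,
) -> AssociationRecord:
    """Median-split log-rank association with overall survival.

    Patients at or below the median expression form the low group (ties go
    low).  Sign ``+`` means the high group has the longer Kaplan–Meier median
    survival (favorable); the effect is the signed −log10 p.  All-censored
    data, or a group with fewer than 2 patients, is flagged not applicable.
    """
    df = pd.concat(
        {"x": expression, "t": os_days, "e": os_event}, axis=1, join="inner"
    ).dropna()
    n = len(df)
    if n < 4 or df["e"].sum() < 1:
        return _not_applicable(mirna_id, ENDPOINT_SURVIVAL, n)
    high = df["x"] > df["x"].median()
    if high.sum() < 2 or (~high).sum() < 2:
        return _not_applicable(mirna_id, ENDPOINT_SURVIVAL, n)
    res = logrank_test(
        df.loc[high, "t"],
        df.loc[~high, "t"],
        event_observed_A=df.loc[high, "e"],
        event_observed_B=df.loc[~high, "e"],
    )
    p = float(res.p_value)
    med_high = _km_median(df.loc[high, "t"].to_numpy(), df.loc[high, "e"].to_numpy())
    med_low = _km_median(df.loc[~high, "t"].to_numpy(), df.loc[~high, "e"].to_numpy())
    if med_high > med_low:
        direction = 1.0
    elif med_high < med_low:
        direction = -1.0
    else:
        # undefined or tied medians: fall back to event-rate comparison
        rate_high = df.loc[high, "e"].mean()
        rate_low = df.loc[~high, "e"].mean()
        direction = 1.0 if rate_high < rate_low else (-1.0 if rate_high > rate_low else 0.0)
    effect = direction * (-math.log10(max(p, _P_FLOOR)))
    sign = ("+" if direction > 0 else "-") if (p < alpha and direction != 0) else "0"
    return AssociationRecord(mirna_id, ENDPOINT_SURVIVAL, effect, sign, p, n)


def stage_association(
    mirna_id: str,
    expression: pd.Series,
    stage: pd.Series,
    endpoint: str = ENDPOINT_T,
    alpha: float = 0.05,
) -> AssociationRecord:
    """Spearman correlation of expression with an ordinal stage (1–4).

    Effect is Spearman rho; sign follows rho when p < alpha.  Constant stage
    (or expression) is flagged not applicable.
    """
    df = pd.concat({"x": expression, "s": stage}, axis=1, join="inner").dropna()
    n = len(df)
    if n < 3 or df["s"].nunique() < 2 or df["x"].nunique() < 2:
        return _not_applicable(mirna_id, endpoint, n)
    rho, p = stats.spearmanr(df["x"], df["s"])
    rho, p = float(rho), float(p)
    sign = ("+" if rho > 0 else "-") if (p < alpha and rho != 0) else "0"
    return AssociationRecord(mirna_id, endpoint, rho, sign, p, n)


def metastasis_association(
    mirna_id: str,
    expression: pd.Series,
    m_stage: pd.Series,
    alpha: float = 0.05,
) -> AssociationRecord:
    """Two-sided Mann–Whitney U between M0 and M1 patients.

    Effect is the rank-biserial correlation 2*U1/(n1*n0) − 1 (positive when
    M1 tumors express more); sign gates on p < alpha.  An empty group is
    flagged not applicable.
    """
    df = pd.concat({"x": expression, "m": m_stage}, axis=1, join="inner").dropna()
    x0 = df.loc[df["m"] == 0, "x"].to_numpy()
    x1 = df.loc[df["m"] == 1, "x"].to_numpy()
    n = len(x0) + len(x1)
    if len(x0) == 0 or len(x1) == 0:
        return _not_applicable(mirna_id, ENDPOINT_M, n)
    # exact U distribution when feasible (small tie-free samples)
    no_ties = len(np.unique(np.concatenate([x0, x1]))) == n
    method = "exact" if (no_ties and max(len(x0), len(x1)) <= 25) else "asymptotic"
    u1, p = stats.mannwhitneyu(x1, x0, alternative="two-sided", method=method)
    effect = float(2.0 * u1 / (len(x1) * len(x0)) - 1.0)
    p = float(p)
    med_diff = np.median(x1) - np.median(x0)
    direction = np.sign(med_diff) if med_diff != 0 else np.sign(effect)
    sign = ("+" if direction > 0 else "-") if (p < alpha and direction != 0) else "0"
    return AssociationRecord(mirna_id, ENDPOINT_M, effect, sign, p, n)


def classify_biomarker(records: Mapping[str, AssociationRecord]) -> BiomarkerCall:
    """Combine the four endpoint records into a biomarker call.

    Requires at least two significant endpoints, all with the same
    orientation (oncogenic: survival −, stages +, M +; suppressor mirrored).
    Mixed significant orientations give ``none`` with a conflict flag.
    ``promising`` additionally requires all three endpoint groups (survival;
    T or pathological stage; M) to be significant.
    """
    missing = [e for e in ENDPOINTS if e not in records]
    if missing:
        raise ValueError(f"records missing endpoints {missing}")
    mirna_id = records[ENDPOINTS[0]].mirna_id
    sig = [e for e in ENDPOINTS if records[e].significant]
    orientations = {
        ONCOGENIC if records[e].sign == _ONCO_SIGNS[e] else SUPPRESSOR for e in sig
    }
    conflict = len(orientations) > 1
    if len(sig) >= 2 and not conflict:
        klass = orientations.pop()
    else:
        klass = NONE
    groups = (
        ENDPOINT_SURVIVAL in sig,
        ENDPOINT_T in sig or ENDPOINT_P in sig,
        ENDPOINT_M in sig,
    )
    promising = klass != NONE and all(groups)
    return BiomarkerCall(mirna_id, klass, tuple(sig), promising, conflict)


def _direction_membership(
    records: Mapping[str, AssociationRecord], direction: str
) -> tuple[bool, bool, bool]:
    """(survival, stage-group, M) significance with the given orientation."""
    def oriented(e: str) -> bool:
        r = records[e]
        if not r.significant:
            return False
        is_onco = r.sign == _ONCO_SIGNS[e]
        return is_onco if direction == ONCOGENIC else not is_onco

    return (
        oriented(ENDPOINT_SURVIVAL),
        oriented(ENDPOINT_T) or oriented(ENDPOINT_P),
        oriented(ENDPOINT_M),
    )


def volcano_and_venn(
    all_records: Mapping[str, Mapping[str, AssociationRecord]],
) -> tuple[dict[str, pd.DataFrame], dict[str, dict[str, int]]]:
    """Per-endpoint volcano tables and 3-set Venn counts per direction class.

    Venn sets, in key order survival / stage / M: region keys are binary
    strings, e.g. ``"110"`` = significant for survival and stage but not M
    with the given orientation.  Returned for both the oncogenic
    (poor-prognosis) and suppressor (favorable) orientation.
    """
    if not all_records:
        raise ValueError("no miRNAs screened")
    volcano: dict[str, pd.DataFrame] = {}
    for endpoint in ENDPOINTS:
        rows = []
        for mirna_id in sorted(all_records):
            r = all_records[mirna_id][endpoint]
            rows.append(
                {
                    "mirna_id": mirna_id,
                    "effect": r.effect,
                    "neg_log10_p": -math.log10(max(r.p, _P_FLOOR))
                    if r.applicable and r.p == r.p
                    else float("nan"),
                    "p": r.p,
                    "sign": r.sign,
                    "significant": r.significant,
                    "n_used": r.n_used,
                }
            )
        volcano[endpoint] = pd.DataFrame(rows)
    venn: dict[str, dict[str, int]] = {}
    for direction in (ONCOGENIC, SUPPRESSOR):
        counts = {f"{a}{b}{c}": 0 for a in "01" for b in "01" for c in "01"}
        counts.pop("000")
        for mirna_id, records in all_records.items():
            member = _direction_membership(records, direction)
            key = "".join("1" if m else "0" for m in member)
            if key != "000":
                counts[key] += 1
        venn[direction] = counts
    return volcano, venn


class PrognosticScreen:
    """Model object for the cohort-wide signed biomarker screen.

    Parameters
    ----------
    dataset
        :class:`CohortDataset` with aligned expression and clinical tables.
    alpha
        Two-sided significance level per endpoint (raw p-values by default).
    min_expressed_samples
        Expression-prevalence filter: a miRNA must be detected in more than
        this many patients.
    bh_correct
        When True, Benjamini–Hochberg-adjust p-values across miRNAs within
        each endpoint before signing.
    """

    def __init__(
        self,
        dataset: CohortDataset,
        alpha: float = 0.05,
        min_expressed_samples: int = 300,
        bh_correct: bool = False,
    ) -> None:
        if not (0 < alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        self.dataset = dataset
        self.alpha = alpha
        self.min_expressed_samples = min_expressed_samples
        self.bh_correct = bh_correct

    @classmethod
    def from_files(
        cls, expression_path: str, clinical_path: str, **kwargs
    ) -> "PrognosticScreen":
        from .io import read_clinical, read_mirna_matrix

        return cls(
            CohortDataset(read_mirna_matrix(expression_path), read_clinical(clinical_path)),
            **kwargs,
        )

    def _associations_for(self, mirna_id: str, expr: pd.Series) -> dict[str, AssociationRecord]:
        clin = self.dataset.clinical
        return {
            ENDPOINT_SURVIVAL: survival_association(
                mirna_id, expr, clin["os_days"], clin["os_event"], self.alpha
            ),
            ENDPOINT_T: stage_association(
                mirna_id, expr, clin["t_stage"], ENDPOINT_T, self.alpha
            ),
            ENDPOINT_P: stage_association(
                mirna_id, expr, clin["p_stage"], ENDPOINT_P, self.alpha
            ),
            ENDPOINT_M: metastasis_association(
                mirna_id, expr, clin["m_stage"], self.alpha
            ),
        }

    def fit(self) -> "ScreenResults":
        expr = filter_mirnas(self.dataset.expression, self.min_expressed_samples)
        records: dict[str, dict[str, AssociationRecord]] = {}
        for mirna_id, row in expr.iterrows():
            records[str(mirna_id)] = self._associations_for(str(mirna_id), row)
        if self.bh_correct and records:
            records = self._bh_adjust(records)
        calls = {m: classify_biomarker(r) for m, r in records.items()}
        return ScreenResults(records, calls, self.alpha)

    def _bh_adjust(
        self, records: dict[str, dict[str, AssociationRecord]]
    ) -> dict[str, dict[str, AssociationRecord]]:
        from dataclasses import replace

        mirnas = sorted(records)
        for endpoint in ENDPOINTS:
            applicable = [m for m in mirnas if records[m][endpoint].applicable]
            if not applicable:
                continue
            ps = np.array([records[m][endpoint].p for m in applicable])
            qs = stats.false_discovery_control(ps, method="bh")
            # q >= p, so q < alpha implies the raw sign was already nonzero
            for m, q in zip(applicable, qs):
                r = records[m][endpoint]
                sign = r.sign if q < self.alpha else "0"
                records[m][endpoint] = replace(r, p=float(q), sign=sign)
        return records


class ScreenResults:
    """Fitted screen: per-endpoint associations, biomarker calls, Venn/volcano."""

    def __init__(
        self,
        records: dict[str, dict[str, AssociationRecord]],
        calls: dict[str, BiomarkerCall],
        alpha: float,
    ) -> None:
        self.records = records
        self.calls = calls
        self.alpha = alpha

    @property
    def associations(self) -> pd.DataFrame:
        rows = []
        for mirna_id in sorted(self.records):
            for endpoint in ENDPOINTS:
                r = self.records[mirna_id][endpoint]
                rows.append(
                    {
                        "mirna_id": mirna_id,
                        "endpoint": endpoint,
                        "effect": r.effect,
                        "sign": r.sign,
                        "p": r.p,
                        "n_used": r.n_used,
                        "applicable": r.applicable,
                    }
                )
        return pd.DataFrame(rows)

    @property
    def calls_table(self) -> pd.DataFrame:
        """Table-1-shaped calls: one row per miRNA with per-endpoint signs."""
        rows = []
        for mirna_id in sorted(self.calls):
            r = self.records[mirna_id]
            c = self.calls[mirna_id]
            rows.append(
                {
                    "mirna_id": mirna_id,
                    "survival_sign": r[ENDPOINT_SURVIVAL].sign,
                    "t_stage_sign": r[ENDPOINT_T].sign,
                    "p_stage_sign": r[ENDPOINT_P].sign,
                    "m_stage_sign": r[ENDPOINT_M].sign,
                    "class": c.klass,
                    "promising": c.promising,
                    "conflict": c.conflict,
                    "n_significant": len(c.endpoints_significant),
                }
            )
        return pd.DataFrame(rows)

    def volcano(self) -> dict[str, pd.DataFrame]:
        return volcano_and_venn(self.records)[0]

    def venn_counts(self) -> dict[str, dict[str, int]]:
        return volcano_and_venn(self.records)[1]

    def summary(self) -> str:
        table = self.calls_table
        n_onco = int((table["class"] == ONCOGENIC).sum())
        n_supp = int((table["class"] == SUPPRESSOR).sum())
        n_prom = int(table["promising"].sum())
        lines = [
            "Prognostic miRNA screen",
            "=======================",
            f"miRNAs screened:     {len(table)}",
            f"alpha:               {self.alpha}",
            f"oncogenic pattern:   {n_onco}",
            f"suppressor pattern:  {n_supp}",
            f"promising (3 groups):{n_prom:>2}",
        ]
        for _, row in table[table["promising"]].iterrows():
            lines.append(
                f"  {row['mirna_id']}: survival {row['survival_sign']}, "
                f"T {row['t_stage_sign']}, P {row['p_stage_sign']}, "
                f"M {row['m_stage_sign']} -> {row['class']}"
            )
        return "\n".join(lines)
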
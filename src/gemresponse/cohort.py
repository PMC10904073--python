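"""Clinical curation: drug standardization, exclusions, response binarization.

The curation rules reproduce how a usable drug-response cohort is distilled
from messy clinical records: free-text drug names are standardized against
a synonym dictionary; patients are kept only if they have at least one
record of the target drug, a non-missing best response, internally
consistent responses, and treatment that started after tumor procurement
(tumors profiled before exposure to the drug). Best response is then
binarized RECIST-style: complete or partial response (CR/PR) = responder,
stable or progressive disease (SD/PD) = nonresponder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_RESPONSES = ("CR", "PR", "SD", "PD")
RESPONDER_CODES = ("CR", "PR")

#: exclusion rules, applied in this fixed order (order affects only the
#: per-rule tallies, never the surviving patient set)
EXCLUSION_RULES = ("no_target_drug", "missing_response", "inconsistent_response", "pre_resection_treatment")


def standardize_drug_names(
    records: pd.DataFrame, synonym_map: Dict[str, str]
) -> pd.DataFrame:
    """Map free-text drug names to canonical names.

    Matching is case-insensitive and whitespace-trimmed against
    *synonym_map* (lower-cased variant -> canonical). Unmapped names pass
    through unchanged with a logged warning — curation is lenient by
    design, since an unmapped drug simply fails the drug filter later.
    """
    records = records.copy()
    normalized = records["drug_name"].astype(str).str.strip().str.lower()
    mapped = normalized.map(synonym_map)
    unmapped = records.loc[mapped.isna(), "drug_name"].unique()
    if len(unmapped):
        logger.warning("unmapped drug names pass through unchanged: %s", list(unmapped))
    records["drug_name"] = mapped.fillna(records["drug_name"])
    return records


def binarize_response(best_response: str) -> str:
    """CR/PR -> responder; SD/PD -> nonresponder. Missing must be filtered first."""
    if best_response not in VALID_RESPONSES:
        raise ValueError(
            f"cannot binarize best response {best_response!r}; "
            f"expected one of {VALID_RESPONSES} (filter missing responses first)"
        )
    return "responder" if best_response in RESPONDER_CODES else "nonresponder"


def filter_cohort(
    records: pd.DataFrame, drug: str = "gemcitabine"
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Apply the four exclusion rules; return the cohort and per-rule tallies.

    Rules, in order: (1) keep only patients with >= 1 record of the target
    drug; (2) drop patients whose response to it is missing; (3) drop
    patients whose multiple records of the drug binarize inconsistently
    (PR + CR is consistent — the label, not the raw code, is what models
    see); (4) drop patients treated before tumor procurement. One row per
    surviving patient. Tallies count *patients* removed by each rule, so
    they sum to input minus output patients.
    """
    tallies = {rule: 0 for rule in EXCLUSION_RULES}
    all_patients = records["patient_id"].unique()
    drug_records = records[records["drug_name"] == drug]
    with_drug = drug_records["patient_id"].unique()
    tallies["no_target_drug"] = len(all_patients) - len(with_drug)

    surviving = []
    for pid, group in drug_records.groupby("patient_id", sort=True):
        responses = group["best_response"].astype(str)
        if (~responses.isin(VALID_RESPONSES)).any():
            tallies["missing_response"] += 1
            continue
        labels = {binarize_response(r) for r in responses}
        if len(labels) > 1:
            tallies["inconsistent_response"] += 1
            continue
        if (group["treatment_start"] < group["procurement_day"]).any():
            tallies["pre_resection_treatment"] += 1
            continue
        first = group.iloc[0]
        row = {
            "patient_id": pid,
            "response_label": labels.pop(),
            "best_response": first["best_response"],
        }
        for col in ("os_time", "os_event", "pfs_time", "pfs_event"):
            if col in group.columns:
                row[col] = first[col]
        surviving.append(row)
    cohort = pd.DataFrame(surviving)
    if cohort.empty:
        logger.warning("curation produced an empty cohort for drug %r", drug)
    return cohort, tallies


@dataclass
class MatchedDataset:
    """A profile matrix aligned with curated labels, ready for modeling."""

    X: pd.DataFrame  # samples x features, index = sample IDs
    y: np.ndarray  # 1 = responder, aligned to X rows
    patient_ids: List[str]
    n_unmatched_samples: int = 0
    n_unmatched_patients: int = 0

    @property
    def sample_ids(self) -> List[str]:
        return [str(s) for s in self.X.index]

    @property
    def n_samples(self) -> int:
        return len(self.X)


def truncate_barcode(sample_id: str, length: int = 12) -> str:
    """Patient-level prefix of a sample barcode (TCGA patient IDs: 12 chars)."""
    return str(sample_id)[:length]


def join_profile_to_cohort(
    profile, cohort: pd.DataFrame, barcode_length: int = 12
) -> MatchedDataset:
    """Inner-join a profile with the curated cohort on the patient barcode.

    Sample IDs are truncated to their patient-level prefix before matching.
    Samples without a label and labeled patients without a sample are
    dropped and counted. If a patient contributes several samples, the
    first after sorting sample IDs is kept (warned).
    """
    values = profile.values
    sample_to_patient = {s: truncate_barcode(s, barcode_length) for s in values.index}
    cohort_ids = set(cohort["patient_id"].astype(str))

    chosen: Dict[str, str] = {}
    duplicates = 0
    for sid in sorted(values.index, key=str):
        pid = sample_to_patient[sid]
        if pid not in cohort_ids:
            continue
        if pid in chosen:
            duplicates += 1
            continue
        chosen[pid] = sid
    if duplicates:
        logger.warning("%d duplicate samples per patient dropped (kept first sorted)", duplicates)

    matched_pids = [pid for pid in cohort["patient_id"].astype(str) if pid in chosen]
    n_unmatched_patients = len(cohort_ids) - len(matched_pids)
    n_unmatched_samples = len(values) - len(matched_pids) - duplicates

    rows = [chosen[pid] for pid in matched_pids]
    X = values.loc[rows]
    label_map = dict(zip(cohort["patient_id"].astype(str), cohort["response_label"]))
    y = np.array([1 if label_map[pid] == "responder" else 0 for pid in matched_pids])
    return MatchedDataset(
        X=X,
        y=y,
        patient_ids=matched_pids,
        n_unmatched_samples=n_unmatched_samples,
        n_unmatched_patients=n_unmatched_patients,
    )
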
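"""Per-patient response classification: modified PERCIST and PCWG3.

Molecular-imaging response is classified on the percent change of
whole-body TLP or MTV with modified PERCIST bands: partial remission (PR)
is a decrease of more than 30%, progressive disease (PD) an increase of
more than 30% *or* the appearance of new metastases, stable disease (SD)
anything in between. Biochemical response uses the PCWG3 bands on serum
PSA: PR below -50%, PD above +25%, SD between. Band boundaries are strict
(exactly -30% is SD, exactly +25% is SD). Classification always uses
unrounded percent changes; the 1-d.p. values in exports are display only.

The PCWG3 confirmation by a second PSA measurement is deliberately
omitted: classification is on a single post-therapy value, matching the
single-follow-up design this pipeline quantifies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("psmaquant")

IMAGING_BAND_PCT = 30.0
PSA_PR_PCT = -50.0
PSA_PD_PCT = 25.0


class Response(str, Enum):
    PR = "PR"
    SD = "SD"
    PD = "PD"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class PatientRecord:
    """Pre/post burden and PSA values for one patient.

    TLP in mL x SUV, MTV in mL, PSA in ng/mL. ``new_metastases`` is the
    (possibly manually adjudicated) new-lesion flag; it overrides any
    imaging percent change to PD.
    """

    patient_id: str
    tlp_pre: float
    tlp_post: float
    mtv_pre: float
    mtv_post: float
    psa_pre: float
    psa_post: float
    new_metastases: bool = False

    def __post_init__(self) -> None:
        for name in ("tlp_pre", "tlp_post", "mtv_pre", "mtv_post", "psa_pre", "psa_post"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative for patient {self.patient_id}")


@dataclass(frozen=True)
class ResponseCall:
    patient_id: str
    delta_tlp_pct: float
    delta_mtv_pct: float
    delta_psa_pct: float
    tlp_response: Response
    mtv_response: Response
    psa_response: Response
    new_metastases: bool

    @property
    def imaging_response(self) -> Response:
        """Headline imaging call (the TLP verdict; MTV is reported alongside)."""
        return self.tlp_response


def percent_change(pre: float, post: float) -> float:
    """100 x (post - pre) / pre; undefined (rejected) for pre <= 0."""
    if pre <= 0:
        raise ValueError(f"percent change undefined for non-positive baseline value {pre}")
    if post < 0:
        raise ValueError("post value must be non-negative")
    return 100.0 * (post - pre) / pre


def classify_imaging(delta_pct: float, new_metastases: bool = False) -> Response:
    """Modified PERCIST on a whole-body burden change.

    PD whenever new metastases appeared, regardless of the burden change.
    """
    if not np.isfinite(delta_pct):
        raise ValueError("delta must be finite")
    if new_metastases or delta_pct > IMAGING_BAND_PCT:
        return Response.PD
    if delta_pct < -IMAGING_BAND_PCT:
        return Response.PR
    return Response.SD


def classify_psa(delta_pct: float) -> Response:
    """PCWG3 biochemical response on the PSA change (single measurement)."""
    if not np.isfinite(delta_pct):
        raise ValueError("delta must be finite")
    if delta_pct < PSA_PR_PCT:
        return Response.PR
    if delta_pct > PSA_PD_PCT:
        return Response.PD
    return Response.SD


def classify_record(record: PatientRecord) -> ResponseCall:
    d_tlp = percent_change(record.tlp_pre, record.tlp_post)
    d_mtv = percent_change(record.mtv_pre, record.mtv_post)
    d_psa = percent_change(record.psa_pre, record.psa_post)
    call = ResponseCall(
        patient_id=record.patient_id,
        delta_tlp_pct=d_tlp, delta_mtv_pct=d_mtv, delta_psa_pct=d_psa,
        tlp_response=classify_imaging(d_tlp, record.new_metastases),
        mtv_response=classify_imaging(d_mtv, record.new_metastases),
        psa_response=classify_psa(d_psa),
        new_metastases=record.new_metastases,
    )
    if call.tlp_response is not call.mtv_response:
        logger.warning("patient %s: TLP verdict %s disagrees with MTV verdict %s",
                       record.patient_id, call.tlp_response, call.mtv_response)
    return call


@dataclass(frozen=True)
class CohortAssessment:
    calls: tuple[ResponseCall, ...]
    frequencies: pd.DataFrame  # index PR/SD/PD, columns tlp/mtv/psa counts + pct
    rejected: tuple[tuple[str, str], ...]  # (patient_id, reason)

    @property
    def n(self) -> int:
        return len(self.calls)


def response_frequencies(calls: Sequence[ResponseCall]) -> pd.DataFrame:
    """PR/SD/PD counts and percentages per method."""
    idx = [Response.PR.value, Response.SD.value, Response.PD.value]
    out = pd.DataFrame(index=pd.Index(idx, name="response"))
    for method in ("tlp", "mtv", "psa"):
        counts = pd.Series([getattr(c, f"{method}_response").value for c in calls]).value_counts()
        out[f"{method}_n"] = [int(counts.get(r, 0)) for r in idx]
        out[f"{method}_pct"] = [round(100.0 * counts.get(r, 0) / len(calls), 1) for r in idx]
    return out


def assess_cohort(records: Iterable[PatientRecord]) -> CohortAssessment:
    """Classify every patient and tabulate per-method response frequencies.

    Records with a non-positive baseline value (percent change undefined)
    are rejected individually with a logged reason; the run continues.
    """
    records = list(records)
    if not records:
        raise ValueError("cohort must contain at least one record")
    calls: list[ResponseCall] = []
    rejected: list[tuple[str, str]] = []
    for record in records:
        try:
            calls.append(classify_record(record))
        except ValueError as exc:
            logger.warning("rejecting patient %s: %s", record.patient_id, exc)
            rejected.append((record.patient_id, str(exc)))
    if not calls:
        raise ValueError("no classifiable records in cohort")
    return CohortAssessment(calls=tuple(calls),
                            frequencies=response_frequencies(calls),
                            rejected=tuple(rejected))


def calls_to_frame(calls: Sequence[ResponseCall]) -> pd.DataFrame:
    """Per-patient change/response table (deltas displayed to 1 d.p.).

    The ``new_metastases`` column carries the asterisk semantics of the
    per-patient flag; ``waterfall_rank`` orders patients by descending
    TLP change for waterfall plotting.
    """
    frame = pd.DataFrame([{
        "patient_id": c.patient_id,
        "delta_tlp_pct": round(c.delta_tlp_pct, 1),
        "delta_mtv_pct": round(c.delta_mtv_pct, 1),
        "delta_psa_pct": round(c.delta_psa_pct, 1),
        "tlp_response": c.tlp_response.value,
        "mtv_response": c.mtv_response.value,
        "psa_response": c.psa_response.value,
        "new_metastases": c.new_metastases,
    } for c in calls])
    frame["waterfall_rank"] = frame["delta_tlp_pct"].rank(ascending=False, method="first").astype(int)
    return frame


def read_cohort_csv(path) -> list[PatientRecord]:
    """Load the cohort CSV contract.

    Header: patient_id, tlp_pre, tlp_post, mtv_pre, mtv_post, psa_pre,
    psa_post, new_metastases (true/false).
    """
    frame = pd.read_csv(path)
    required = {"patient_id", "tlp_pre", "tlp_post", "mtv_pre", "mtv_post",
                "psa_pre", "psa_post", "new_metastases"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"cohort CSV is missing columns: {sorted(missing)}")
    records = []
    for _, row in frame.iterrows():
        nm = row["new_metastases"]
        if isinstance(nm, str):
            nm = nm.strip().lower() in ("true", "1", "yes")
        records.append(PatientRecord(
            patient_id=str(row["patient_id"]),
            tlp_pre=float(row["tlp_pre"]), tlp_post=float(row["tlp_post"]),
            mtv_pre=float(row["mtv_pre"]), mtv_post=float(row["mtv_post"]),
            psa_pre=float(row["psa_pre"]), psa_post=float(row["psa_post"]),
            new_metastases=bool(nm),
        ))
    return records
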
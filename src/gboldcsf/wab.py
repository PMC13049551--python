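"""Western Aphasia Battery (WAB) scoring.

Raw subtest scores are converted to four scaled domain scores, each on a
0-10 range, and combined into the Aphasia Quotient (AQ, 0-100):

* spontaneous speech = speech fluency + information content (two 0-10
  subtests, so the domain runs 0-20);
* comprehension = (yes/no questions + auditory word recognition +
  sequential order) / 20;
* repetition = repetition / 10;
* naming = (object naming + word fluency + sentence completion +
  responsive naming) / 10;
* AQ = 2 * (spontaneous + comprehension + repetition + naming),
  giving the 0-100 quotient (20 + 10 + 10 + 10 doubled).

All weights and denominators are configurable, since WAB adaptations
(e.g. translated versions) scale some domains differently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import WAB_SUBTESTS

__all__ = ["DomainWeights", "scale_domains", "aphasia_quotient", "delta_scores",
           "score_table", "DOMAINS"]

DOMAINS = ("spontaneous", "comprehension", "repetition", "naming")


@dataclass
class DomainWeights:
    """Subtest-to-domain weights: domain = sum(w_s * raw_s) / denominator."""

    spontaneous: dict[str, float] = field(
        default_factory=lambda: {"speech_fluency": 1.0, "information_content": 1.0}
    )
    spontaneous_den: float = 1.0
    comprehension: dict[str, float] = field(
        default_factory=lambda: {
            "yes_no_questions": 1.0,
            "auditory_word_recognition": 1.0,
            "sequential_order": 1.0,
        }
    )
    comprehension_den: float = 20.0
    repetition: dict[str, float] = field(default_factory=lambda: {"repetition": 1.0})
    repetition_den: float = 10.0
    naming: dict[str, float] = field(
        default_factory=lambda: {
            "object_naming": 1.0,
            "word_fluency": 1.0,
            "sentence_completion": 1.0,
            "responsive_naming": 1.0,
        }
    )
    naming_den: float = 10.0


def scale_domains(
    raw: dict[str, float], weights: DomainWeights | None = None
) -> dict[str, float]:
    """Scaled domain scores from raw subtest scores.

    Raw scores outside [0, max] for their subtest are rejected. Only the
    subtests referenced by the weights are required.
    """
    weights = weights or DomainWeights()
    for name, value in raw.items():
        if name in WAB_SUBTESTS:
            mx = WAB_SUBTESTS[name]["max"]
            if not (0 <= value <= mx):
                raise ValueError(
                    f"raw {name}={value} outside its score range [0, {mx}]"
                )
    out = {}
    for domain in DOMAINS:
        w: dict[str, float] = getattr(weights, domain)
        den: float = getattr(weights, f"{domain}_den")
        missing = [s for s in w if s not in raw]
        if missing:
            raise ValueError(f"domain {domain} missing subtests: {missing}")
        out[domain] = sum(w[s] * raw[s] for s in w) / den
    return out


def aphasia_quotient(domains: dict[str, float]) -> float:
    """AQ = 2 * (spontaneous + comprehension + repetition + naming), 0-100.

    Spontaneous speech enters as the 0-20 sum of its two subtests; the
    other three domains are on 0-10, so the doubled sum tops out at 100.
    """
    missing = [d for d in DOMAINS if d not in domains]
    if missing:
        raise ValueError(f"missing domain scores: {missing}")
    aq = 2.0 * (
        domains["spontaneous"]
        + domains["comprehension"]
        + domains["repetition"]
        + domains["naming"]
    )
    return float(aq)


def score_table(
    raw: pd.DataFrame, suffix: str = "", weights: DomainWeights | None = None
) -> pd.DataFrame:
    """Apply domain scaling and AQ row-wise to a table of raw subtest columns.

    Subtest columns are named ``<subtest><suffix>``; the returned frame has
    ``subject_id`` plus ``<domain><suffix>`` and ``AQ<suffix>`` columns.
    """
    rows = []
    for _, rec in raw.iterrows():
        values = {
            s: float(rec[f"{s}{suffix}"])
            for s in WAB_SUBTESTS
            if f"{s}{suffix}" in raw.columns
        }
        domains = scale_domains(values, weights)
        row = {"subject_id": rec["subject_id"]}
        row.update({f"{d}{suffix}": v for d, v in domains.items()})
        row[f"AQ{suffix}"] = aphasia_quotient(domains)
        rows.append(row)
    return pd.DataFrame(rows)


def delta_scores(pre: pd.DataFrame, post: pd.DataFrame) -> pd.DataFrame:
    """Post-minus-pre change table on matched ``subject_id`` rows.

    Unmatched subjects are excluded (their ids logged); duplicated ids are
    an error. All numeric columns common to both tables are differenced.
    """
    import logging

    logger = logging.getLogger(__name__)
    for name, df in (("pre", pre), ("post", post)):
        if df["subject_id"].duplicated().any():
            dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
            raise ValueError(f"duplicate subject ids in {name} table: {dupes}")
    common = sorted(set(pre["subject_id"]) & set(post["subject_id"]))
    dropped = sorted(set(pre["subject_id"]) ^ set(post["subject_id"]))
    if dropped:
        logger.info("excluding %d unmatched subject(s): %s", len(dropped), dropped)
    pre_m = pre.set_index("subject_id").loc[common]
    post_m = post.set_index("subject_id").loc[common]
    num_cols = [
        c for c in pre_m.columns
        if c in post_m.columns and np.issubdtype(pre_m[c].dtype, np.number)
    ]
    delta = (post_m[num_cols] - pre_m[num_cols]).reset_index()
    return delta
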
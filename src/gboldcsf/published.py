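"""Reference summary statistics of the clinical cohort this package models.

These are printed group-level numbers (means, SDs, counts) transcribed
from the source study's tables; they serve as fixed inputs for
reproducibility checks of the in-table arithmetic and as anchors for
generator defaults. No individual-level data are included.
"""

from __future__ import annotations

__all__ = [
    "WAB_TABLE",
    "WAB_DOMAIN_ROWS",
    "AGE_SUMMARY",
    "COUPLING_EFFECTS",
]

# Treated-cohort WAB scores (n = 14): mean and SD before and after a
# 4-week speech-language therapy programme. Domain rows are the 0-20 / 0-10
# scaled scores; subtest rows are raw scores.
WAB_TABLE: dict[str, dict[str, float]] = {
    "AQ":                        {"pre_mean": 46.13, "pre_sd": 13.16, "post_mean": 70.25, "post_sd": 10.30, "t": 9.606},
    "spontaneous":               {"pre_mean": 7.13,  "pre_sd": 1.64,  "post_mean": 12.15, "post_sd": 2.01,  "t": 5.212},
    "speech_fluency":            {"pre_mean": 3.14,  "pre_sd": 1.75,  "post_mean": 5.57,  "post_sd": 2.31,  "t": 3.426},
    "information_content":       {"pre_mean": 4.00,  "pre_sd": 1.52,  "post_mean": 6.57,  "post_sd": 1.16,  "t": 4.746},
    "comprehension":             {"pre_mean": 5.69,  "pre_sd": 1.39,  "post_mean": 7.63,  "post_sd": 1.13,  "t": 6.423},
    "yes_no_questions":          {"pre_mean": 45.29, "pre_sd": 6.83,  "post_mean": 48.57, "post_sd": 8.83,  "t": 1.674},
    "auditory_word_recognition": {"pre_mean": 44.45, "pre_sd": 8.49,  "post_mean": 53.58, "post_sd": 3.40,  "t": 4.652},
    "sequential_order":          {"pre_mean": 25.57, "pre_sd": 20.47, "post_mean": 48.93, "post_sd": 17.89, "t": 5.120},
    "repetition_domain":         {"pre_mean": 7.17,  "pre_sd": 1.53,  "post_mean": 8.80,  "post_sd": 1.04,  "t": 4.603},
    "repetition":                {"pre_mean": 71.72, "pre_sd": 15.32, "post_mean": 88.03, "post_sd": 10.44, "t": 4.603},
    "naming":                    {"pre_mean": 3.01,  "pre_sd": 1.47,  "post_mean": 6.53,  "post_sd": 1.99,  "t": 5.190},
    "object_naming":             {"pre_mean": 17.64, "pre_sd": 12.00, "post_mean": 48.29, "post_sd": 13.30, "t": 7.737},
    "word_fluency":              {"pre_mean": 5.71,  "pre_sd": 2.61,  "post_mean": 8.43,  "post_sd": 2.21,  "t": 3.153},
    "sentence_completion":       {"pre_mean": 2.79,  "pre_sd": 2.36,  "post_mean": 6.86,  "post_sd": 2.28,  "t": 4.251},
    "responsive_naming":         {"pre_mean": 1.29,  "pre_sd": 1.64,  "post_mean": 5.71,  "post_sd": 3.17,  "t": 4.460},
}

#: The four scaled domain rows entering the Aphasia Quotient.
WAB_DOMAIN_ROWS = ("spontaneous", "comprehension", "repetition_domain", "naming")

# Demographics: age mean, SD and n per group.
AGE_SUMMARY = {"HC": (48.00, 9.14, 35), "PSA": (46.50, 9.45, 20)}

# Reported coupling effect sizes (Cohen's d).
COUPLING_EFFECTS = {"PSA_vs_HC": 0.55, "pre_vs_post": 0.67}
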
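"""Small builders shared by test modules."""

import numpy as np
import pandas as pd


def paired_cohort_with_counts(rng, n_subjects=6, n_genes=40):
    """Minimal paired cohort: metadata, integer counts, and dummy scores."""
    rows = []
    for i in range(n_subjects):
        for tp in ("pre", "post"):
            rows.append({
                "sample": f"P{i}_{tp}", "subject": f"P{i}", "group": "early-RA",
                "timepoint": tp, "treatment": "MTX", "response": "responder",
                "age": 50.0, "pct_dup": float(rng.uniform(0.1, 0.3)),
                "gc_score": float(rng.normal()),
            })
    cohort = pd.DataFrame(rows).set_index("sample")
    counts = pd.DataFrame(
        rng.poisson(50, size=(n_genes, len(cohort))),
        index=[f"g{j}" for j in range(n_genes)],
        columns=cohort.index,
    )
    scores = pd.DataFrame(
        rng.uniform(0.1, 1.0, size=(len(cohort), 3)),
        index=cohort.index,
        columns=["cellA", "cellB", "cellC"],
    )
    return counts, cohort, scores
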
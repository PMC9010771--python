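"""Screen report rendering: tables, QQ-plot data and λ summaries.

Plots are emitted as the underlying data tables (expected vs observed
−log10 p), so no graphics stack is required; any plotting tool can render
them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .screen import ScreenResult


def qq_data(pvalues) -> pd.DataFrame:
    """Expected vs observed −log10 p for a QQ plot (ascending expected)."""
    p = np.sort(np.asarray(list(pvalues), dtype=float))
    n = len(p)
    if n == 0:
        raise ValueError("no p-values to plot")
    expected = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame({
        "expected_neglog10_p": -np.log10(expected),
        "observed_neglog10_p": -np.log10(np.maximum(p, 1e-300)),
    })


def render_report(result: ScreenResult, out) -> None:
    """Write the screen outputs into directory ``out``.

    Files: ``screen_table.tsv`` (per-metabolite estimates and filter
    verdicts), ``qq_data.tsv`` (filtered analyses), ``hits.tsv``,
    ``lambda.json`` (λ before/after, Bonferroni thresholds, config snapshot)
    and one sensitivity JSON per hit.
    """
    if result.rows.empty:
        raise ValueError("empty screen result")
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    result.rows.to_csv(out / "screen_table.tsv", sep="\t", index=False)
    passing = result.rows[result.rows["passed_filter"]]
    qq = qq_data(passing["p"]) if len(passing) else qq_data(result.rows["p"])
    qq.to_csv(out / "qq_data.tsv", sep="\t", index=False)
    hits = result.rows[result.rows["exposure_id"].isin(result.hits)]
    hits.to_csv(out / "hits.tsv", sep="\t", index=False)
    with open(out / "lambda.json", "w") as fh:
        json.dump({
            "lambda_before": result.lambda_before,
            "lambda_after": result.lambda_after,
            "bonferroni_alpha_filtered": result.bonferroni_alpha,
            "bonferroni_alpha_all": result.bonferroni_alpha_all,
            "n_tested": result.n_tested,
            "n_passing": result.n_passing,
            "hits": result.hits,
            "config": result.config.to_dict(),
        }, fh, indent=2)
    for hit in result.hits:
        rep = result.sensitivity.get(hit)
        if rep is not None:
            (out / f"sensitivity_{hit}.json").write_text(rep.to_json(indent=2))
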
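"""qPCR-derived enrichment statistics: ddCt folds, percent input, pulldown ratios.

Conventions: amplification efficiency defaults to 2.0 (one cycle = one
doubling) and is exposed as a parameter; technical-replicate Ct values are
averaged before any delta is taken (per-replicate deltas are available behind
a flag); NaN inputs propagate to NaN outputs rather than being dropped.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

CT_COLUMNS = ("sample", "target", "ct")
DEFAULT_REFERENCE = "18S"


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a Ct table TSV with columns sample, target, ct (replicates as rows)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns: {sorted(missing)}")
    return df


def _mean_ct(ct: pd.DataFrame, sample: str, target: str) -> float:
    rows = ct[(ct["sample"] == sample) & (ct["target"] == target)]
    if rows.empty:
        raise KeyError(f"no Ct values for sample {sample!r}, target {target!r}")
    return float(rows["ct"].mean())


def ddct_relative_abundance(
    ct: pd.DataFrame,
    treated: str,
    control: str,
    target: str,
    reference: str = DEFAULT_REFERENCE,
    efficiency: float = 2.0,
    per_replicate: bool = False,
) -> float:
    """Fold change of ``target`` in ``treated`` vs ``control`` by the ddCt method.

    fold = efficiency ** -[(Ct_target,t - Ct_ref,t) - (Ct_target,c - Ct_ref,c)];
    values above 1 mean accumulation in the treated sample. By default
    replicate Cts are averaged first; with ``per_replicate`` the ddCt is
    computed per replicate index and the folds averaged.
    """
    if efficiency <= 1.0:
        raise ValueError("amplification efficiency must exceed 1")
    if per_replicate:
        folds = []
        groups = [
            ct[(ct["sample"] == s) & (ct["target"] == t)]["ct"].to_numpy()
            for s, t in (
                (treated, target), (treated, reference),
                (control, target), (control, reference),
            )
        ]
        if any(len(g) == 0 for g in groups):
            raise KeyError(f"missing amplicon for ddCt of {target!r}")
        n = min(len(g) for g in groups)
        for i in range(n):
            ddct = (groups[0][i] - groups[1][i]) - (groups[2][i] - groups[3][i])
            folds.append(efficiency ** -ddct)
        return float(np.mean(folds))
    ddct = (
        _mean_ct(ct, treated, target) - _mean_ct(ct, treated, reference)
    ) - (_mean_ct(ct, control, target) - _mean_ct(ct, control, reference))
    return float(efficiency ** -ddct)


def percent_input_enrichment(
    ct: pd.DataFrame,
    ip_sample: str,
    input_sample: str,
    target: str,
    input_fraction: float = 0.1,
    efficiency: float = 2.0,
) -> float:
    """Percent of input recovered in an immunoprecipitation, from qPCR Cts.

    The input Ct is first adjusted for the fraction of lysate it represents
    (dilution of 1/f costs log_eff(1/f) cycles), then
    %input = 100 * efficiency ** (Ct_input_adjusted - Ct_ip).
    """
    if not 0.0 < input_fraction <= 1.0:
        raise ValueError("input_fraction must be in (0, 1]")
    if efficiency <= 1.0:
        raise ValueError("amplification efficiency must exceed 1")
    ct_input = _mean_ct(ct, input_sample, target)
    ct_ip = _mean_ct(ct, ip_sample, target)
    adjustment = math.log(1.0 / input_fraction, efficiency)
    return float(100.0 * efficiency ** ((ct_input - adjustment) - ct_ip))


def pulldown_ratio(
    signal_a: Sequence[float] | float, signal_b: Sequence[float] | float
) -> tuple[float, float]:
    """Per-replicate ratio a/b of paired signals; returns (mean, sample SD).

    Used for pulldown-efficiency comparisons (e.g. knockdown vs control
    eluate signals) and for normalization against a carrier-protein control;
    the ratio is taken per replicate pair, then averaged. SD is NaN for a
    single replicate.
    """
    a = np.atleast_1d(np.asarray(signal_a, dtype=float))
    b = np.atleast_1d(np.asarray(signal_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("replicate pairs must align")
    if np.any(b == 0):
        raise ValueError("zero denominator signal")
    ratios = a / b
    sd = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else float("nan")
    return float(np.mean(ratios)), sd


def write_results(path: str | Path, rows: list[dict]) -> None:
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
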
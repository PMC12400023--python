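"""Published ring-trial inputs used in worked examples.

Summary statistics and product-mean tables published for the LED-HDRS
interlaboratory trial, used as *inputs* to the criterion and bias
arithmetic (the raw per-measurement data behind them are not public).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "ring_product_means",
    "RING_SUMMARY_UVAPF_STUDY1",
]

#: Published ln-scale summary statistics of the first-trial UVA-PF
#: evaluation used in worked examples: the persistent lab bias of product
#: group 1, the group-4 bias with its decision limit, and the cross-group
#: bias dispersion with the consistency limit.
RING_SUMMARY_UVAPF_STUDY1 = {
    "pg1_s_L_pers": 0.27,
    "AL": 0.3,
    "pg4_group_bias": 0.31,
    "pg4_DL": 0.3,
    "bias_sd_across_groups": 0.042,
    "CL": 0.093,
}


def ring_product_means(metric: str = "spf") -> pd.DataFrame:
    """Published product-specific mean values (reference vs alternative).

    ``metric`` is ``"spf"`` or ``"uvapf"``.  Columns: ``product_code``,
    ``mean_ref``, ``mean_alt``.
    """
    if metric not in ("spf", "uvapf"):
        raise ValueError("metric must be 'spf' or 'uvapf'")
    name = f"ring_product_means_{metric}.csv"
    with resources.files("hdrskit.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, comment="#")
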
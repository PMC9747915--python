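"""Figure output: phenotype heatmap with dendrogram and split p-value."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster.hierarchy import dendrogram

from radiomit.phenotyping import standardize, ward_cluster

__all__ = ["phenotype_heatmap"]


def phenotype_heatmap(
    features,
    labels: np.ndarray,
    path,
    split_pvalue: float | None = None,
    title: str = "",
) -> None:
    """Save a patients x features heatmap, row-ordered by the Ward tree,
    with the dendrogram alongside and the top-split p-value annotated."""
    import pandas as pd

    x = (
        features.values.to_numpy(dtype=float)
        if hasattr(features, "values") and not isinstance(features, np.ndarray)
        else np.asarray(features, dtype=float)
    )
    if isinstance(x, pd.DataFrame):
        x = x.to_numpy(dtype=float)
    z = standardize(x)
    _, merge = ward_cluster(z, 2, standardize_input=False)

    fig, (ax_d, ax_h) = plt.subplots(
        1, 2, figsize=(10, 6), gridspec_kw={"width_ratios": [1, 4]}
    )
    dn = dendrogram(merge, orientation="left", no_labels=True, ax=ax_d)
    order = [int(i) for i in dn["leaves"]]
    ax_d.set_xticks([])
    im = ax_h.imshow(
        z[order], aspect="auto", cmap="RdBu_r", vmin=-3, vmax=3, origin="lower"
    )
    ax_h.set_xlabel("features")
    ax_h.set_yticks([])
    for side, lab in zip(("left",), (np.asarray(labels)[order],)):
        changes = np.flatnonzero(np.diff(lab)) + 0.5
        for c in changes:
            ax_h.axhline(c, color="black", lw=0.8)
    header = title or "radiomic phenotypes"
    if split_pvalue is not None:
        header += f" (top-split p = {split_pvalue:.3g})"
    fig.suptitle(header)
    fig.colorbar(im, ax=ax_h, shrink=0.6, label="z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
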
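"""Morphometric summaries, PCA and assembly of the analytical table.

PCA is run on standardised traits (correlation matrix, complete cases).
Two trait presets ship: ``"four"`` (mass, body length, head length, tail
length — the default, matching the reported size/shape axes) and
``"eight"`` (mass, body length, chest circumference, shoulder height and
the four paw widths). The sign convention flips any component whose loading
sum is negative, so a general size axis always loads positively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError

PCA_TRAIT_PRESETS = {
    "four": ["mass_kg", "body_length_cm", "head_length_cm", "tail_length_cm"],
    "eight": [
        "mass_kg", "body_length_cm", "chest_circ_cm", "shoulder_height_cm",
        "front_paw_w_l_cm", "front_paw_w_r_cm", "hind_paw_w_l_cm", "hind_paw_w_r_cm",
    ],
}


def trait_correlations(morpho: pd.DataFrame, traits: list[str]) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix of the given traits."""
    return morpho[traits].corr(method="pearson", min_periods=3)


@dataclass
class PCAResult:
    trait_names: list[str]
    loadings: pd.DataFrame    # trait x component
    scores: pd.DataFrame      # complete-case bears x component, indexed by AnimalID
    explained_pct: np.ndarray
    n_complete: int


def fit_pca(morpho: pd.DataFrame, traits: list[str] | str = "four") -> PCAResult:
    """Correlation-matrix PCA on standardised traits, complete cases only."""
    if isinstance(traits, str):
        traits = PCA_TRAIT_PRESETS[traits]
    data = morpho.set_index("AnimalID")[traits] if "AnimalID" in morpho.columns else morpho[traits]
    complete = data.dropna()
    p = len(traits)
    if len(complete) < p + 1:
        missing = data.isna().sum()
        raise InsufficientDataError(
            f"PCA needs >= {p + 1} complete cases, got {len(complete)}; "
            f"missing counts per trait: {missing.to_dict()}"
        )
    x = complete.to_numpy(dtype=float)
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    corr = (z.T @ z) / (len(z) - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    flip = eigvec.sum(axis=0) < 0
    eigvec[:, flip] *= -1.0
    comp = [f"PC{i + 1}" for i in range(p)]
    loadings = pd.DataFrame(eigvec, index=traits, columns=comp)
    scores = pd.DataFrame(z @ eigvec, index=complete.index, columns=comp)
    return PCAResult(
        trait_names=list(traits),
        loadings=loadings,
        scores=scores,
        explained_pct=100.0 * eigval / eigval.sum(),
        n_complete=len(complete),
    )


def assemble_table(
    home_ranges: pd.DataFrame,
    morpho: pd.DataFrame,
    usability: dict | None = None,
    pca: PCAResult | None = None,
) -> pd.DataFrame:
    """One analytical row per bear.

    Joins home-range estimates with morphometrics on AnimalID (bears missing
    from the morphometric table are retained with missing trait fields),
    computes ``log_mcp`` (natural log of mcp_km2) and nulls ``kud_km2``
    wherever the usability screen failed, so KUD-based summaries only ever
    see usable individuals while MCP rows preserve the full sample.
    """
    hr = home_ranges.loc[home_ranges["mcp_km2"].notna()].copy()
    morph = morpho.rename(columns={"AnimalID": "animal_id"})
    out = hr.merge(morph, on="animal_id", how="left")
    out["log_mcp"] = np.log(out["mcp_km2"])
    if usability is not None:
        failed = {aid for aid, rep in usability.items() if not rep.overall_pass}
        out.loc[out["animal_id"].isin(failed), "kud_km2"] = np.nan
    if pca is not None:
        scores = pca.scores.rename_axis("animal_id").reset_index()
        keep = ["animal_id"] + [c for c in ("PC1", "PC2") if c in scores.columns]
        out = out.merge(scores[keep], on="animal_id", how="left")
        out = out.rename(columns={"PC1": "pc1", "PC2": "pc2"})
    return out.reset_index(drop=True)
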
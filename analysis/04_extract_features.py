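"""Extract features two ways: PCA at the 95% cumulative-variance rule
(interpretability: which parameters load where) and 4-D UMAP
(n_neighbors=5, min_dist=0; the clustering input).

Reads results/preprocessed/, writes results/features/.
"""

import warnings
from pathlib import Path

import pandas as pd

from chillclass import FeatureMatrix, pca_fit, umap_embed

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 42


def main() -> None:
    out = ROOT / "features"
    out.mkdir(parents=True, exist_ok=True)
    frame = pd.read_csv(ROOT / "preprocessed" / "normalized.csv")
    M = FeatureMatrix.from_frame(frame)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pca = pca_fit(M, variance_threshold=0.95)
    pd.concat([M.sample_meta, pca.scores], axis=1).to_csv(out / "pca_scores.csv", index=False)
    pca.loadings.to_csv(out / "pca_loadings.csv")
    ratios = ", ".join(f"{100 * r:.2f}%" for r in pca.explained_variance_ratio)
    print(f"PCA: {pca.n_components} components ({ratios}; "
          f"cumulative {100 * pca.cumulative:.2f}%)")
    for pc in pca.loadings.columns:
        top = pca.loadings[pc].abs().nlargest(3).index.tolist()
        print(f"  {pc} dominated by {top}")

    emb = umap_embed(M, seed=SEED)
    pd.concat([emb.sample_meta, emb.features], axis=1).to_csv(
        out / "umap_features.csv", index=False)
    print(f"UMAP: 4 features for {M.n_samples} samples (seed {SEED})")


if __name__ == "__main__":
    main()
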
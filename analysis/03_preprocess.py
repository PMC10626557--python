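"""Filter outliers with the 3σ rule (per temperature × day group), min–max
normalize to [0,1], and screen inter-parameter Pearson correlations.

Reads results/derived/, writes results/preprocessed/.
"""

import warnings
from pathlib import Path

import pandas as pd

from chillclass import (
    FeatureMatrix, correlation_strength, filter_outliers_3sigma,
    minmax_normalize, pearson_matrix,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = ROOT / "preprocessed"
    out.mkdir(parents=True, exist_ok=True)
    frame = pd.read_csv(ROOT / "derived" / "derived_parameters.csv")
    M = FeatureMatrix.from_frame(frame)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        M, removed = filter_outliers_3sigma(M)
    Mn = minmax_normalize(M)
    Mn.to_frame().to_csv(out / "normalized.csv", index=False)
    removed.to_csv(out / "removed_outliers.csv", index=False)

    corr = pearson_matrix(Mn)
    corr.to_csv(out / "pearson.csv")
    strong = [
        (a, b, round(corr.loc[a, b], 3), correlation_strength(corr.loc[a, b]))
        for i, a in enumerate(corr.index) for b in corr.columns[i + 1:]
        if abs(corr.loc[a, b]) >= 0.8
    ]
    pd.DataFrame(strong, columns=["a", "b", "r", "strength"]).to_csv(
        out / "extremely_strong_pairs.csv", index=False)

    print(f"retained {M.n_samples} rows; removed {len(removed)} outlier rows")
    print(f"{len(strong)} parameter pairs are extremely strongly correlated "
          "(|r| ≥ 0.8) — the redundancy that motivates feature extraction")


if __name__ == "__main__":
    main()
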
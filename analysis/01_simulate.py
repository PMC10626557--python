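"""Generate the synthetic chilling study: 4 temperatures (8/10/12/14 °C) ×
days 0–5 × 8 plants, base fluorescence signals with planted severity tiers.

Writes results/simulated/{chlf_signals,planted_labels}.csv.
"""

from pathlib import Path

from chillclass import SyntheticConfig, generate_chlf_dataset
from chillclass.chlf import records_to_frame

OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = SyntheticConfig(seed=SEED)
    records, labels = generate_chlf_dataset(config)
    records_to_frame(records, derive=False).to_csv(OUT / "chlf_signals.csv", index=False)
    labels.to_csv(OUT / "planted_labels.csv", index=False)
    counts = labels["planted_class"].value_counts().sort_index()
    print(f"generated {len(records)} records (seed {SEED})")
    print("planted class counts:", dict(counts))


if __name__ == "__main__":
    main()
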
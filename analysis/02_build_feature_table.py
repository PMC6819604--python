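#!/usr/bin/env python
"""Prepare the relative-abundance matrix and age-group profiles.

Reads the cohort from results/cohort/, removes the rarest genera (cumulative
share <= 0.01% of reads), flags dominance outliers, converts to relative
abundances, bins samples into the 14 age groups and computes per-group mean
profiles with a per-genus z-scored variant.  Writes the matrices under
results/feature_table/.
"""

from pathlib import Path

from spdm import feature_table as ft

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "feature_table"
OUT.mkdir(parents=True, exist_ok=True)

counts = ft.read_counts(ROOT / "cohort" / "counts.tsv")
meta = ft.read_metadata(ROOT / "cohort" / "metadata.tsv")

counts, removed = ft.filter_low_abundance(counts, cum_fraction=1e-4)
print(f"low-abundance filter removed {len(removed)} genera; {counts.shape[1]} retained")

rel = ft.to_relative_abundance(counts)
flags = ft.flag_outlier_samples(rel, dominance_threshold=0.8)
print(f"dominance outliers flagged: {len(flags)}")

meta = ft.assign_age_groups(meta.loc[rel.index])
profiles = ft.normalize_features(ft.group_means(rel, meta))
print(
    f"{len(profiles.group_ids)} age groups, sizes "
    + ",".join(str(int(n)) for n in profiles.n_samples)
)

rel.to_csv(
    OUT / "relative_abundance.tsv", sep="\t", index_label="sample_id", float_format="%.6g"
)
meta.to_csv(OUT / "metadata_grouped.tsv", sep="\t", index=False)
profiles.means.to_csv(OUT / "group_profiles.tsv", sep="\t", index_label="group_id")
profiles.normalized.to_csv(
    OUT / "group_profiles_normalized.tsv", sep="\t", index_label="group_id"
)
print(f"written to {OUT}")
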
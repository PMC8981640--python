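"""From per-CpG beta values to the block-level MBS matrix.

Generates a small site-level table (CpG coordinates + betas per sample),
groups neighboring sites into methylation blocks (gap <= 500 bp, >= 3
sites), and averages betas per block — the representation the classifiers
consume.
"""

from too_integrate.methylation import build_blocks, pca_projection
from too_integrate.synthetic import MethylCohortSpec, gen_methylation_sites

sites, _, _ = gen_methylation_sites(
    MethylCohortSpec(n_blocks=60, n_differential=6, seed=3)
)
print(f"site table: {len(sites)} rows "
      f"({sites[['chrom', 'pos']].drop_duplicates().shape[0]} CpGs x "
      f"{sites['sample_id'].nunique()} samples)")

blocks, mbs = build_blocks(sites, max_gap=500, min_sites=3)
print(f"-> {len(blocks)} blocks; matrix {mbs.values.shape[0]} samples x "
      f"{mbs.values.shape[1]} blocks")
print("first block:", blocks[0].block_id, f"({len(blocks[0].member_sites)} CpGs)")
print(mbs.values.iloc[:3, :4].round(3))

coords = pca_projection(mbs, n_components=2)
print("\nPC1/PC2 coordinates of the first 3 samples (QC view):")
print(coords.head(3).round(2))
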
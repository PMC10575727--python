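"""Quantify brush-border continuity via skeleton Feret calipers.

A continuous brush border stains as long ribbons of CD10; disease
tissue shows short, fragmented ribbons. The continuity metric
thresholds the channel, skeletonizes it (pruning branches under 10 px),
and reports the maximum Feret caliper of each skeleton fragment —
longer mean caliper means a more continuous brush border.
"""

from enteroquant import feret_distances, skeletonize_marker
from enteroquant.simulate import ChannelSpec, SyntheticImageConfig, gen_mxif_image

for label, length in [("healthy-like (long fragments)", 90.0),
                      ("disease-like (short fragments)", 30.0)]:
    config = SyntheticImageConfig(
        shape=(300, 300),
        channels={"CD10": ChannelSpec("ribbon", n_fragments=6,
                                      fragment_length=length)},
        seed=1,
    )
    image, _ = gen_mxif_image(config)
    skeletons = skeletonize_marker(image["CD10"], threshold="otsu",
                                   min_branch_length=10)
    summary = feret_distances(skeletons)
    print(f"{label}: {summary.count} fragments, "
          f"mean Feret {summary.mean_px:.1f} px (planted {length:.0f} px)")
print("The mean Feret caliper tracks the planted fragment length: "
      "fragmented staining yields a smaller continuity score.")
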
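"""Compute the 45-feature texture vector for one trabecular ROI.

Shows the 5 intensity-histogram features and, for two quantization levels,
the 5 co-occurrence statistics, comparing a low-density with a high-density
phantom to illustrate which features carry the density signal.
"""

from bonetex import PhantomSpec, extract_features, extract_roi, find_trabecular_roi, generate_phantom

for density in (0.25, 0.75):
    img = generate_phantom(PhantomSpec(density=density, seed=8))
    roi = extract_roi(img, find_trabecular_roi(img))
    fv = extract_features(roi).as_dict()
    print(f"density {density}: {len(fv)} features")
    print("  histogram: " + ", ".join(f"{k.removeprefix('hist_')}={fv[k]:.3f}"
                                      for k in list(fv)[:5]))
    for n in (16, 128):
        stats = {k.split("_")[-1]: v for k, v in fv.items()
                 if k.startswith(f"glcm_{n}_horizontal")}
        print(f"  GLCM N={n:3d} horizontal: "
              + ", ".join(f"{k}={v:.4f}" for k, v in stats.items()))
# Higher density raises the histogram mean and flips the skew (the bone
# phase dominates instead of marrow), while the co-occurrence statistics
# track the texture's mixing; together these let a regression on the
# 45-vector recover bone mineral density.
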
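"""Generate a small synthetic greenhouse scene and inspect its ground truth.

A 2×2 grid of 32 cm pots is imaged by overlapping 512 px frames at three
acquisition days.  The generator also returns pixel-exact plant masks and
trait values computed by an independent brute-force path.
"""

from phenopot.synthetic import SceneConfig, default_varieties, generate_scene

config = SceneConfig(mm_per_px=2.134, grid_rows=2, grid_cols=2,
                     spacing_mm=400.0, frame_px=512, overlap=0.5,
                     canvas_px=1024, days=(0, 17, 34), seed=7)
frames, truth = generate_scene(config, default_varieties(4, seed=7))

print(f"{len(frames)} frames ({len(frames) // len(config.days)} per day), "
      f"{len(truth.pots)} pots")
print("\nPlanting layout (global mm position -> variety/plant):")
print(truth.layout().to_string(index=False))
print("\nGround-truth traits (first rows):")
print(truth.traits[["variety", "plant", "day", "PA", "CA", "CAR", "G",
                    "ExG"]].head(6).round(2).to_string(index=False))
print("\nPA is the projected canopy area in cm²; CAR = PA/convex-hull area "
      "measures canopy compactness; G and ExG summarize leaf greenness.")
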
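"""Render PMC surfaces for the weakest and strongest published policies.

The 3x3 surface arranges the nine first-level values row-major; smooth
rendering interpolates between the anchors without moving them.  The
weakest policy's surface is broadly concave, the strongest nearly flat
at height 1 except the issuer dimension (X3 = 0.25).
"""

from pathlib import Path

from pmceval import build_surface, load_reference_scores, render_surface

out_dir = Path("surfaces")
out_dir.mkdir(exist_ok=True)

reference = load_reference_scores()
scores = {s.policy_id: s for s in reference.scores()}
pmcs = {pid: s.pmc for pid, s in scores.items()}
weakest = min(pmcs, key=pmcs.get)
strongest = max(pmcs, key=pmcs.get)

for pid in (weakest, strongest):
    matrix = build_surface(scores[pid])
    path = render_surface(matrix, out_dir / f"pmc_surface_{pid}.png", interpolation="smooth")
    print(f"{pid}: PMC {pmcs[pid]}, cells:")
    for row in matrix.cells:
        print("   ", [round(float(v), 2) for v in row])
    print(f"  -> {path}")

# Cell heights are the first-level values; mean(cells) * 9 recovers the
# full-precision PMC, so the surface is a lossless view of the score.
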
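"""Every attention group samples exactly M^2 = 49 keys regardless of its
window size: larger windows use proportionally larger dilation.  This
script prints the window/dilation schedule per preset for the four encoder
grids of a 224x224 input."""

from msrunet import auto_group_specs

for preset in ("default", "low", "high"):
    print(f"preset {preset!r}:")
    for side in (56, 28, 14, 7):
        specs = auto_group_specs(side, side, 32, 4, preset=preset)
        sched = ", ".join(f"S={s.window}/D={s.dilation}" for s in specs)
        keys = {s.num_keys for s in specs}
        print(f"  grid {side:2d}x{side:<2d}: {sched}  (keys per group: {keys})")
print()
print("S = D*(M-1)+1 with M=7, so the key budget never changes; only the")
print("spatial reach of each group does.")
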
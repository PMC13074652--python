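"""Generate the synthetic greenhouse dataset and inspect its design.

The generator reproduces the destructive-sampling design of the study:
303 sweet-pepper plants over five growing seasons, three interlighting
treatments (CT none, RB red-blue, FR red-blue + far-red) and sampling
days from 30 to 153 after transplanting.
"""

from pepperfw import SimConfig, generate_dataset, write_records

data = generate_dataset(SimConfig(seed=42))
write_records(data, "scratch_data.csv") if False else None

print(f"records: {len(data)}")
print("\nsamples per season x treatment:")
print(data.groupby(["season", "treatment"]).size().unstack())
print("\ntrait / target summary (medians):")
print(data[["plant_height", "main_stem_len", "shoot_fw", "fruit_fw"]].median().round(1))
# Shoot FW saturates with structure; fruit FW accumulates with time:
print("\ncorrelations:")
sumlen = data[["main_stem_len", "left_stem_len", "right_stem_len"]].sum(axis=1)
print(f"  shoot_fw ~ summed stem length: {data['shoot_fw'].corr(sumlen):.2f}")
print(f"  fruit_fw ~ days after transplanting: {data['fruit_fw'].corr(data['dat'].astype(float)):.2f}")
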
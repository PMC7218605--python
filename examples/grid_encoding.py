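"""Encode a certificate as the padded 6x20 code grid the model consumes.

Part I lines occupy rows 0-3 (immediate cause first), Part II rows 4-5;
cells hold vocabulary indices, with reserved indices for padding and for
codes unseen at training time.  Demographics are factorized into 25 age
bins, 2 genders and 16 years.
"""

import mortcode as mc

vocab = mc.build_vocabulary(["I21", "I251", "E11", "J18", "F179"])

cert = mc.Certificate.build(
    id="example",
    part1=[["I21"], ["I251"], ["E11"]],   # infarction <- ischaemic disease <- diabetes
    part2=[["J18", "F179"]],              # pneumonia, tobacco use as comorbidities
    year=2012, sex=0, age_value=74, age_unit="years",
)

grid = mc.encode_grid(cert, vocab, L=6, W=20)
print("grid shape:", grid.shape)
print("pad index:", vocab.pad_index, "| unknown index:", vocab.unknown_index)
print("non-pad cells (row, col, code):")
for r in range(6):
    for c in range(20):
        if grid[r, c] != vocab.pad_index:
            print(f"  ({r}, {c}) -> {vocab.code_at(int(grid[r, c]))}")

part1, part2 = mc.decode_grid(grid, vocab)
print("decode(encode(cert)) recovers the lines:", part1, part2)

d = cert.demographics
print(f"demographics: age bin {d.age_bin} (of 25), gender {d.gender}, "
      f"year index {d.year_index} (of {d.n_years})")
print("age bin examples:", {
    "10 days": mc.bin_age(10, "days"),     # neonatal period
    "200 days": mc.bin_age(200, "days"),
    "7 years": mc.bin_age(7, "years"),
    "74 years": mc.bin_age(74, "years"),
    "110 years": mc.bin_age(110, "years"),
})
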
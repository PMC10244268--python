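"""Ecological-status boundary conversion: IPS → PDI_SE → total phosphorus.

Runs with no input data: the package ships the published linear relations
between the PDI_SE index and the IPS index (PDI = −0.29·IPS + 8.0536) and
between PDI_SE and log10 TP (PDI = 1.84322·log10 TP + 0.6493).
"""

from pdise import boundary_table

table = boundary_table()
print(table[["eqr", "ips", "pdi", "tp_ugl"]].to_string())
print()
print(
    "Each Swedish status-class boundary (rows) is expressed as an EQR "
    "(IPS / reference IPS), converted to the PDI_SE scale, and inverted to a\n"
    "TP concentration in µg/l. The high/good boundary lands at "
    f"{table.loc['high/good', 'tp_ugl']} µg/l and good/moderate at "
    f"{table.loc['good/moderate', 'tp_ugl']} µg/l; boundaries mapping outside\n"
    "the 4–100 µg/l linear response range are marked 'no response'."
)
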
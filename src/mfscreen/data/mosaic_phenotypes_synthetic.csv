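# Synthetic reconstruction of a per-individual mosaic phenotype table.
# Tallies reproduce the published per-tissue totals (36/21/35 feminized of 39
# mosaics; gonads 33/39); individual-level assignments are invented.
individual_id,group,antennae,maxillary_palps,external_genitalia,gonads
m01,mosaic,feminized,feminized,feminized,feminized
m02,mosaic,feminized,feminized,feminized,feminized
m03,mosaic,feminized,feminized,feminized,feminized
m04,mosaic,feminized,feminized,feminized,feminized
m05,mosaic,feminized,feminized,feminized,feminized
m06,mosaic,feminized,feminized,feminized,feminized
m07,mosaic,feminized,feminized,feminized,feminized
m08,mosaic,feminized,feminized,feminized,feminized
m09,mosaic,feminized,feminized,feminized,feminized
m10,mosaic,feminized,feminized,feminized,feminized
m11,mosaic,feminized,feminized,feminized,feminized
m12,mosaic,feminized,feminized,feminized,feminized
m13,mosaic,feminized,feminized,feminized,feminized
m14,mosaic,feminized,feminized,feminized,feminized
m15,mosaic,feminized,feminized,feminized,feminized
m16,mosaic,feminized,feminized,feminized,feminized
m17,mosaic,feminized,feminized,feminized,feminized
m18,mosaic,feminized,feminized,feminized,feminized
m19,mosaic,feminized,feminized,feminized,feminized
m20,mosaic,feminized,feminized,feminized,feminized
m21,mosaic,feminized,feminized,feminized,feminized
m22,mosaic,normal,feminized,feminized,feminized
m23,mosaic,normal,feminized,feminized,feminized
m24,mosaic,normal,feminized,feminized,feminized
m25,mosaic,normal,feminized,feminized,feminized
m26,mosaic,normal,feminized,feminized,feminized
m27,mosaic,normal,feminized,feminized,feminized
m28,mosaic,normal,feminized,feminized,feminized
m29,mosaic,normal,feminized,feminized,feminized
m30,mosaic,normal,feminized,feminized,feminized
m31,mosaic,normal,feminized,feminized,feminized
m32,mosaic,normal,feminized,feminized,feminized
m33,mosaic,normal,feminized,feminized,feminized
m34,mosaic,normal,feminized,feminized,normal
m35,mosaic,normal,feminized,feminized,normal
m36,mosaic,normal,normal,feminized,normal
m37,mosaic,normal,normal,normal,normal
m38,mosaic,normal,normal,normal,normal
m39,mosaic,normal,normal,normal,normal
c01,control,normal,normal,normal,normal
c02,control,normal,normal,normal,normal
c03,control,normal,normal,normal,normal
c04,control,normal,normal,normal,normal
c05,control,normal,normal,normal,normal
c06,control,normal,normal,normal,normal
c07,control,normal,normal,normal,normal
c08,control,normal,normal,normal,normal
c09,control,normal,normal,normal,normal
c10,control,normal,normal,normal,normal
c11,control,normal,normal,normal,normal
c12,control,normal,normal,normal,normal
c13,control,normal,normal,normal,normal
c14,control,normal,normal,normal,normal
c15,control,normal,normal,normal,normal
c16,control,normal,normal,normal,normal
c17,control,normal,normal,normal,normal
c18,control,normal,normal,normal,normal
c19,control,normal,normal,normal,normal
c20,control,normal,normal,normal,normal
c21,control,normal,normal,normal,normal
c22,control,normal,normal,normal,normal
c23,control,normal,normal,normal,normal
c24,control,normal,normal,normal,normal
c25,control,normal,normal,normal,normal
c26,control,normal,normal,normal,normal
c27,control,normal,normal,normal,normal
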
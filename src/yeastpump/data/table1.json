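{
 "rate_unit": "mL/min",
 "C_msf": 0.0016218,
 "C_ssf": 0.0002183,
 "C_sf": -0.0013759,
 "C_mst": 0.0056424,
 "C_sst": -0.0043008,
 "C_st": 0.022460,
 "C_mti": -22.551974,
 "C_sti": 8.596592,
 "C_ti": 217.890016,
 "C_mte": -250.45527,
 "C_ste": 303.71105,
 "C_te": 1262.644
}
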
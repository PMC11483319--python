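# Infrastructure cost model: EUR 2.5M linac, 10% annual service charge,
# 12-year lifetime, 2.7 patients treated per hour, giving a flat rate of
# EUR 37.72 per delivered gray.  A tumour-bed boost fraction bills 2.67 Gy.
linac_capital: 2500000
annual_service_rate: 0.10
lifetime_years: 12
patients_per_hour: 2.7
rate_per_gy: 37.72
boost_gy_per_fraction: 2.67
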
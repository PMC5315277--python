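label,experiment,treatment,poc_percent,al_percent,al_mass_mg,poc_stock_mg_published,poc_stock_mmol_published,poc_flux_total_published,poc_flux_daily_published,dust_exported_percent_published,litho_flux_total_published
CHIPIE1-NA,CHIPIE 1,NA,1.6,5.3,46.0,13.8,1.1,38.2,6.4,31.0,3100
CHIPIE1-A,CHIPIE 1,A,1.6,5.4,46.8,13.9,1.2,38.7,6.4,31.6,3160
CHIPIE2-NA,CHIPIE 2,NA,1.5,4.9,108.4,32.4,2.7,90.1,15.0,73.1,7310
CHIPIE2-A,CHIPIE 2,A,1.5,5.1,109.2,31.3,2.6,87.1,14.5,73.7,7370
CHIPIE3-NA,CHIPIE 3,NA,1.3,4.4,81.1,24.3,2.0,67.5,11.3,54.6,5460
CHIPIE3-A,CHIPIE 3,A,1.6,4.9,91.8,29.4,2.5,81.7,13.6,61.9,6190
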
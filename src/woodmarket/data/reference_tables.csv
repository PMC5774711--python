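# Reference values for validating simulated study-region statistics.
# Transcribed printed summary values: official statistics on harvested wood
# (annual averages and coefficients of variation, 2004-2014) and
# practitioner-survey results (means with inter-quartile ranges) for public
# forest managers, sawmill operators and energy wood buyers.
# Priorities follow the published rules: annual amounts below 1000 m3/yr are
# low priority; low amount combined with high variation is omitted.
variable,mean,iqr_lo,iqr_hi,unit,priority,group
pfm_requests_in_sawlogs,5,2,9,requests/yr,high,pfm_survey
pfm_requests_in_energy,12,1,20,requests/yr,high,pfm_survey
pfm_requests_in_industrial,1,0,2,requests/yr,medium,pfm_survey
pfm_rejection_rate_sawlogs,25,0,40,%,high,pfm_survey
pfm_rejection_rate_energy,20,0,40,%,high,pfm_survey
pfm_rejection_rate_industrial,30,0,50,%,medium,pfm_survey
pfm_reserved_share_sawlogs,42,,,%,high,pfm_survey
pfm_reserved_share_energy,55,,,%,high,pfm_survey
pfm_reserved_share_industrial,25,,,%,high,pfm_survey
private_own_consumption_sawlogs,10,,,%,high,pfm_survey
private_own_consumption_energy,60,,,%,high,pfm_survey
private_own_consumption_industrial,5,,,%,high,pfm_survey
sawmill_stock_utilization,64,,,%,high,sawmill_survey
sawmill_transport_cost_share,15,12,17,%,high,sawmill_survey
sawmill_supply_perimeter,43,25,50,km,high,sawmill_survey
sawmill_requests_in,25,6,43,requests/yr,high,sawmill_survey
sawmill_requests_out,10,2,14,requests/yr,high,sawmill_survey
sawmill_share_public,42,20,66,%,high,sawmill_survey
sawmill_share_bundler,38,6,52,%,high,sawmill_survey
sawmill_share_trader,20,14,26,%,high,sawmill_survey
sawmill_delivery_per_public_supplier,600,250,950,m3/yr,high,sawmill_survey
sawmill_delivery_per_bundler_supplier,3700,1063,5600,m3/yr,high,sawmill_survey
sawmill_delivery_per_trader_supplier,1150,400,1570,m3/yr,high,sawmill_survey
energy_supply_perimeter,15,5,20,km,high,energy_survey
energy_requests_in,1.5,,,requests/yr,medium,energy_survey
energy_requests_out,1,,,requests/yr,medium,energy_survey
energy_softwood_share,85,,,%,high,energy_survey
production_public_sawlogs_soft,249097,,,m3/yr,high,statistics
production_public_sawlogs_hard,311,,,m3/yr,low,statistics
production_public_energy_soft,65747,,,m3/yr,high,statistics
production_public_energy_hard,14130,,,m3/yr,high,statistics
production_public_industrial_soft,7492,,,m3/yr,medium,statistics
production_public_industrial_hard,328,,,m3/yr,omitted,statistics
production_private_sawlogs_soft,21089,,,m3/yr,high,statistics
production_private_sawlogs_hard,126,,,m3/yr,omitted,statistics
production_private_energy_soft,5779,,,m3/yr,medium,statistics
production_private_energy_hard,4318,,,m3/yr,medium,statistics
production_private_industrial_soft,538,,,m3/yr,low,statistics
production_private_industrial_hard,200,,,m3/yr,omitted,statistics
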
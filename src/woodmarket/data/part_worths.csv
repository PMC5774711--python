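# Reference part-worth utilities and acceptance thresholds (beta0) per
# decision model; criterion scales are documented in the decision module.
model,criterion,beta
supplier_sell,amount_available,1.0
supplier_sell,amount_in_demand,0.5
supplier_sell,trust,1.5
supplier_sell,margin,3.0
supplier_sell,beta0,3.3
sawmill_buy,urgency,1.5
sawmill_buy,order_size,0.3
sawmill_buy,trust,0.8
sawmill_buy,price,2.0
sawmill_buy,beta0,0.5
sawmill_sell,stock_utilization,1.0
sawmill_sell,price,2.0
sawmill_sell,trust,0.5
sawmill_sell,beta0,0.4
energy_buy,urgency,1.5
energy_buy,price,1.5
energy_buy,trust,0.8
energy_buy,beta0,0.4
industrial_buy,urgency,1.5
industrial_buy,price,1.5
industrial_buy,trust,0.8
industrial_buy,beta0,0.4
trader_buy,price,2.0
trader_buy,trust,0.5
trader_buy,beta0,0.35
trader_sell,price,2.0
trader_sell,trust,0.5
trader_sell,beta0,0.1
bundler_buy,margin,2.0
bundler_buy,beta0,0.1
bundler_sell,margin,2.0
bundler_sell,beta0,0.1
importer_sell,price,4.0
importer_sell,beta0,0.0
exporter_buy,price,4.0
exporter_buy,beta0,0.0
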
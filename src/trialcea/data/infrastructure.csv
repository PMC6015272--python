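item,annual_cost
domain_names,93
website_hosting,3600
website_maintenance,19200
ssl_certificate,120
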
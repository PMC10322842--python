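country,cluster
South Africa,African
Australia,Anglo
Canada,Anglo
Ireland,Anglo
New Zealand,Anglo
United Kingdom,Anglo
United States of America,Anglo
United Arab Emirates,Arabic
China,Confucian Asia
Hong Kong,Confucian Asia
Singapore,Confucian Asia
Taiwan,Confucian Asia
Czech Republic,East Europe
Hungary,East Europe
Poland,East Europe
Romania,East Europe
Russian Federation,East Europe
Slovakia,East Europe
Ukraine,East Europe
India,Far East
Indonesia,Far East
Iran,Far East
Malaysia,Far East
Philippines,Far East
Thailand,Far East
Austria,Germanic
Germany,Germanic
Switzerland,Germanic
Argentina,Latin America
Brazil,Latin America
Chile,Latin America
Colombia,Latin America
Costa Rica,Latin America
Mexico,Latin America
Belgium,Latin Europe
France,Latin Europe
Italy,Latin Europe
Portugal,Latin Europe
Spain,Latin Europe
Greece,Near East
Turkey,Near East
Denmark,Nordic
Finland,Nordic
Netherlands,Nordic
Norway,Nordic
Sweden,Nordic
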
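name,code
Corn,1
Cotton,2
Rice,3
Sorghum,4
Soybeans,5
Sunflower,6
Peanuts,10
Tobacco,11
Sweet Corn,12
Pop or Orn Corn,13
Mint,14
Barley,21
Durum Wheat,22
Spring Wheat,23
Winter Wheat,24
Other Small Grains,25
Dbl Crop WinWht/Soybeans,26
Rye,27
Oats,28
Millet,29
Speltz,30
Canola,31
Flaxseed,32
Safflower,33
Rape Seed,34
Mustard,35
Alfalfa,36
Other Hay/Non Alfalfa,37
Camelina,38
Buckwheat,39
Sugarbeets,41
Dry Beans,42
Potatoes,43
Other Crops,44
Sugarcane,45
Sweet Potatoes,46
Misc Vegs & Fruits,47
Watermelons,48
Onions,49
Cucumbers,50
Chick Peas,51
Lentils,52
Peas,53
Tomatoes,54
Caneberries,55
Hops,56
Herbs,57
Clover/Wildflowers,58
Sod/Grass Seed,59
Switchgrass,60
Fallow/Idle Cropland,61
Woodland,63
Cherries,66
Peaches,67
Apples,68
Grapes,69
Christmas Trees,70
Other Tree Crops,71
Citrus,72
Pecans,74
Almonds,75
Walnuts,76
Pears,77
Nonag/Undefined,81
Wetlands,87
Aquaculture,92
Open Water,111
Perennial Ice/Snow,112
Developed/Open Space,121
Developed/Low Intensity,122
Developed/Med Intensity,123
Developed/High Intensity,124
Barren,131
Deciduous Forest,141
Evergreen Forest,142
Mixed Forest,143
Shrubland,152
Grass/Pasture,176
Woody Wetlands,190
Herbaceous Wetlands,195
Pistachios,204
Triticale,205
Carrots,206
Asparagus,207
Garlic,208
Cantaloupes,209
Prunes,210
Olives,211
Oranges,212
Honeydew Melons,213
Broccoli,214
Avocados,215
Peppers,216
Pomegranates,217
Nectarines,218
Greens,219
Plums,220
Strawberries,221
Squash,222
Apricots,223
Vetch,224
Dbl Crop WinWht/Corn,225
Dbl Crop Oats/Corn,226
Lettuce,227
Dbl Crop Triticale/Corn,228
Pumpkins,229
Dbl Crop Lettuce/Durum Wht,230
Dbl Crop Lettuce/Cantaloupe,231
Dbl Crop Lettuce/Cotton,232
Dbl Crop Lettuce/Barley,233
Dbl Crop Durum Wht/Sorghum,234
Dbl Crop Barley/Sorghum,235
Dbl Crop WinWht/Sorghum,236
Dbl Crop Barley/Corn,237
Dbl Crop WinWht/Cotton,238
Dbl Crop Soybeans/Cotton,239
Dbl Crop Soybeans/Oats,240
Dbl Crop Corn/Soybeans,241
Blueberries,242
Cabbage,243
Cauliflower,244
Celery,245
Radishes,246
Turnips,247
Eggplants,248
Gourds,249
Cranberries,250
Dbl Crop Barley/Soybeans,254
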
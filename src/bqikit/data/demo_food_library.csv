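food_id,name,energy_kcal_per_100g,carb_g,simple_sugar_g,fat_g,mufa_g,sfa_g,protein_g,calcium_mg_per_100g,groups,is_beverage,is_energy_beverage
white_bread,White bread,265,49,3,3.2,0.6,0.7,9,25,cereal,0,0
wholegrain_bread,Wholegrain bread,247,41,4,3.5,0.8,0.7,13,40,cereal,0,0
toast_rusk,Toasted rusk,410,75,6,6,2.5,1,11,30,cereal,0,0
breakfast_cereal_sugar,Sugared breakfast cereal,380,84,30,2.5,0.8,0.6,6,15,cereal;sugar_rich,0,0
muesli,Muesli,360,62,14,8,3.5,1.5,10,50,cereal,0,0
oat_flakes,Oat flakes,370,59,1,7,2.6,1.3,13,55,cereal,0,0
biscuit_maria,Maria biscuits,436,75,22,12,5,4,7,20,cereal;sugar_rich,0,0
croissant,Croissant,440,45,12,25,9,12,8,35,cereal;sugar_rich,0,0
pastry_chocolate,Chocolate pastry,470,52,28,26,9,13,6,40,sugar_rich,0,0
madeleine,Madeleine sponge,460,51,26,25,10,5,6,45,sugar_rich,0,0
whole_milk,Whole milk,63,4.7,4.7,3.6,1.0,2.3,3.2,118,dairy,1,1
semi_milk,Semi-skimmed milk,47,4.8,4.8,1.6,0.45,1.0,3.3,120,dairy,1,1
skim_milk,Skimmed milk,35,4.9,4.9,0.2,0.05,0.1,3.4,122,dairy,1,1
milk_cocoa,Milk with soluble cocoa,85,12.5,12.0,1.7,0.5,1.0,3.3,115,dairy;sugar_rich,1,1
milkshake,Milkshake,90,12,11,2.8,0.8,1.8,3.1,100,dairy;sugar_rich,1,1
yogurt_plain,Plain yogurt,61,4.7,4.7,3.3,0.9,2.1,3.8,121,dairy,0,0
yogurt_sweet,Sweetened yogurt,92,13.5,13,2.8,0.8,1.8,3.5,110,dairy;sugar_rich,0,0
cheese_fresh,Fresh cheese,98,3.5,3.5,4.5,1.2,2.9,11,185,dairy,0,0
orange_juice_fresh,Fresh orange juice,45,10.4,8.5,0.2,0.04,0.03,0.7,11,fruit_or_vegetable,1,1
juice_packaged,Packaged fruit juice,48,11.5,11,0.1,0.02,0.02,0.3,8,sugar_rich,1,1
soft_drink_cola,Cola soft drink,42,10.6,10.6,0,0,0,0,2,sugar_rich,1,1
water,Water,0,0,0,0,0,0,0,3,other,1,0
apple,Apple,52,14,10,0.2,0.01,0.03,0.3,6,fruit_or_vegetable,0,0
banana,Banana,89,23,12,0.3,0.03,0.11,1.1,5,fruit_or_vegetable,0,0
orange,Orange,47,12,9,0.1,0.02,0.02,0.9,40,fruit_or_vegetable,0,0
tomato,Tomato,18,3.9,2.6,0.2,0.03,0.03,0.9,10,fruit_or_vegetable,0,0
olive_oil,Virgin olive oil,884,0,0,100,73,14,0,1,olive_oil,0,0
butter,Butter,717,0.1,0.1,81,21,51,0.9,24,butter_margarine,0,0
margarine,Margarine,717,0.4,0.4,80,36,17,0.2,8,butter_margarine,0,0
ham_serrano,Serrano ham,195,0.1,0.1,11,5,3.8,23,10,other,0,0
egg_omelette,Plain omelette,154,0.6,0.6,12,4.8,3.4,11,50,other,0,0
lunch_mixed,Mixed lunch plate,180,18,2,8,3.5,2.5,9,30,other,0,0
dinner_mixed,Mixed dinner plate,160,15,2,7,3,2.2,9,35,other,0,0
snack_sandwich,Ham sandwich,240,30,3,8,3.2,2.6,10,40,other,0,0
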
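event_id,attestation,citation
assistance_org_funding_inadequate,text_attested,availability narrative (donations)
assistance_site_closures,placeholder,fixture convention (subtree interior)
benefit_cyberinfrastructure_down,text_attested,availability narrative
benefit_program_funding_cut,placeholder,fixture convention (subtree interior)
bikes_unavailable,text_attested,gate definitions (AND example)
critical_roads_closed,text_attested,winter storm case study
decreased_net_income,text_attested,accessibility narrative
decreased_supply,text_attested,accessibility narrative; drought case study (transfer from production)
decreased_water,text_attested,drought case study
delivery_truck_access_blocked,text_attested,winter storm case study (delivery trucks stuck)
direct_food_donations_decline,text_attested,availability narrative (donations)
distribution_centers_disrupted,placeholder,subtree 8 caption
distribution_disrupted,text_attested,availability narrative (distribution); winter storm case study
distribution_driver_shortage,text_attested,availability narrative (distribution)
distribution_fuel_unavailable,text_attested,availability narrative (distribution)
distribution_storage_failure,text_attested,availability narrative (distribution)
donation_funding_inadequate,text_attested,availability narrative (donations)
donation_system_failure,text_attested,availability narrative
economic_inaccessibility,text_attested,accessibility narrative
extreme_weather_climate_event,text_attested,drought case study
farm_business_failure,text_attested,drought case study
farm_closures_widespread,text_attested,drought case study (farm counts stable)
farm_labor_force_unavailable,text_attested,availability narrative (farm labor)
food_bank_donation_failure,text_attested,availability narrative (donations)
food_distasteful,text_attested,acceptability narrative
food_inaccessible,text_attested,main tree; accessibility narrative
food_medically_contraindicated,text_attested,acceptability narrative
food_not_culturally_appropriate,text_attested,acceptability narrative
food_not_nutritionally_adequate,text_attested,acceptability narrative
food_purveyor_not_accessible,text_attested,accessibility narrative; winter storm case study
food_system_failure,text_attested,main tree
food_unacceptable,text_attested,acceptability narrative
food_unavailable,text_attested,availability narrative (population-dependent gate)
fuel_cost_spike,text_attested,accessibility narrative
high_food_prices,text_attested,accessibility narrative; drought case study
illness_or_disability_confines_residents,text_attested,accessibility narrative
import_supply_shortfall,placeholder,fixture convention (subtree interior)
increased_costs_passed_on,text_attested,accessibility narrative
input_contamination,text_attested,availability narrative (production inputs)
input_price_spike,text_attested,availability narrative (production inputs)
living_wage_erosion,text_attested,accessibility narrative
mandated_seclusion,text_attested,accessibility narrative
monetary_donations_decline,text_attested,availability narrative (donations)
motor_vehicles_unavailable,text_attested,gate definitions (AND example)
no_purveyor_in_proximity,text_attested,accessibility narrative
other_assistance_donation_failure,text_attested,subtree 11 caption
physical_inaccessibility,text_attested,accessibility narrative
pollinator_population_collapse,text_attested,availability narrative (production inputs)
processing_business_failure,text_attested,availability narrative (processing)
processing_contamination,text_attested,availability narrative (processing)
processing_disrupted,text_attested,availability narrative (processing)
processing_equipment_damaged,text_attested,availability narrative (processing)
processing_labor_shortage,text_attested,availability narrative (processing)
processing_space_unusable,text_attested,availability narrative (processing)
processing_utilities_failure,text_attested,availability narrative (processing)
production_failure,text_attested,availability narrative; drought case study
productivity_decreases,text_attested,drought case study
public_transit_unavailable,text_attested,subtree 3 caption; winter storm case study
purveyors_beyond_walking_inaccessible,text_attested,gate definitions (AND example)
resource_depletion,text_attested,drought case study
retail_business_failure,text_attested,availability narrative (retail)
retail_disrupted,text_attested,availability narrative (retail)
retail_equipment_failure,text_attested,availability narrative (retail)
retail_staff_shortage,text_attested,availability narrative (retail)
retail_utilities_failure,text_attested,availability narrative (retail)
roads_are_obstructed,text_attested,winter storm case study
safety_concerns_prevent_travel,text_attested,accessibility narrative
safety_net_failure,text_attested,accessibility narrative; availability narrative (benefit cards)
season_yield_collapse,placeholder,fixture convention (threshold encoding)
single_season_failure,text_attested,drought case study
supply_chain_cost_increase,placeholder,fixture convention (subtree interior)
supply_chain_failure,text_attested,"main tree, supply chain subtree"
transit_service_suspended,text_attested,"winter storm case study (2-day shutdown, 96 h recovery)"
transport_disruption,text_attested,winter storm case study
unable_to_leave_home,text_attested,accessibility narrative
unemployment_rises,text_attested,accessibility narrative
wholesale_business_failure,text_attested,availability narrative (wholesale)
wholesale_disrupted,text_attested,availability narrative (wholesale)
wholesale_labor_shortage,text_attested,availability narrative (wholesale)
wholesale_services_failure,text_attested,availability narrative (wholesale)
wholesale_space_equipment_failure,text_attested,availability narrative (wholesale)
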